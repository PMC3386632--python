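"""Protein FASTA input/output and header metadata parsing.

Records follow a salivary-proteomics naming convention in which the first
header token is a 5-letter uppercase organism code joined to a numeric
identifier by an underscore (e.g. ``TRIIN_155029178`` for *Triatoma
infestans*).  The convention is treated as opportunistic metadata: headers
that do not match it are still accepted, with an empty organism code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

#: Canonical residue alphabet: the 20 standard amino acids plus X (unknown).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")

_HEADER_RE = re.compile(r"^([A-Z]{5})_(\d+)$")


class FastaError(ValueError):
    """Raised for malformed FASTA content (duplicates, illegal residues)."""


@dataclass
class SequenceRecord:
    """One protein entry.

    Attributes
    ----------
    id:
        Unique text identifier within a collection.
    organism_code:
        5-letter uppercase organism tag, or ``""`` when the header does not
        follow the code_number convention.
    taxon_label:
        Free-text taxon (taken from the header description), or ``""``.
    description:
        Remainder of the header line after the identifier token.
    residues:
        Upper-case residue string over the 20 amino acids plus X.
    """

    id: str
    residues: str
    organism_code: str = ""
    taxon_label: str = ""
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def validate(self) -> None:
        if not self.id:
            raise FastaError("record has an empty identifier")
        if not self.residues:
            raise FastaError(f"record {self.id!r} has an empty sequence")
        for offset, ch in enumerate(self.residues, start=1):
            if ch not in ALPHABET:
                raise FastaError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {offset}"
                )


def parse_header(header: str) -> tuple[str, str, str]:
    """Split a FASTA description line into (id, organism_code, taxon_label).

    The first whitespace token is the identifier.  If it matches the
    5-uppercase-letters + ``_`` + digits convention, the 5-letter prefix is
    returned as the organism code; otherwise the code is empty.  The rest of
    the line becomes the taxon label / description.
    """
    header = header.strip()
    if not header:
        raise FastaError("empty FASTA header")
    parts = header.split(None, 1)
    ident = parts[0]
    rest = parts[1].strip() if len(parts) > 1 else ""
    m = _HEADER_RE.match(ident)
    organism_code = m.group(1) if m else ""
    return ident, organism_code, rest


def _record_from_seqio(rec) -> SequenceRecord:
    ident, code, rest = parse_header(rec.description or rec.id)
    residues = str(rec.seq).upper().rstrip("*")
    return SequenceRecord(
        id=ident,
        residues=residues,
        organism_code=code,
        taxon_label=rest,
        description=rest,
    )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file into validated records, order preserved.

    Residues are upper-cased and a terminal ``*`` stop character is stripped.
    Gap characters or other non-alphabet symbols raise :class:`FastaError`
    naming the record and offset; so does a duplicated identifier.  An empty
    file yields an empty list.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        srec = _record_from_seqio(rec)
        srec.validate()
        if srec.id in seen:
            raise FastaError(f"duplicate identifier {srec.id!r} in {path}")
        seen.add(srec.id)
        records.append(srec)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA with sequence lines wrapped at ``wrap`` columns.

    Round-trip property: ``read_fasta`` on the output reproduces the ids and
    residues byte-exactly.
    """
    if wrap < 1:
        raise ValueError("wrap must be a positive integer")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            header = rec.id
            desc = rec.description or rec.taxon_label
            if desc:
                header += f" {desc}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i : i + wrap] + "\n")
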