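"""Integrin-target annotation, duodegrin flagging, and the database table.

Each tripeptide motif class is mapped to the integrins (and hence cell
types) that disintegrins carrying it are reported to inhibit: RGD-class
motifs block the platelet fibrinogen receptor αIIbβ3, the vitronectin
receptor αvβ3 and the fibronectin receptor α5β1; MLD targets the leukocyte
integrins α4β1, α4β7 and α9β1; KTS/RTS are selective for the collagen-IV
receptor α1β1.  The mapping is putative and ships as editable data, not
code.

A sequence carrying two or more *distinct* tripeptide motifs is flagged as
a duodegrin.  Same-motif multiplicity (e.g. two RGDs in one precursor) is
reported through the match count but is not flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .motifs import MatchTable, MotifMatch
from .seqio import SequenceRecord

# tripeptide -> (integrin targets, cell targets); tuple order is canonical
# and preserved in all serialized output.
DEFAULT_ANNOTATION_TABLE: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "RGD": (("αIIbβ3", "αvβ3", "α5β1"), ("platelets", "endothelial cells")),
    "KGD": (("αIIbβ3",), ("platelets",)),
    "WGD": (("αIIbβ3", "αvβ3", "α5β1"), ("platelets", "endothelial cells")),
    "MLD": (("α4β1", "α4β7", "α9β1"), ("leukocytes",)),
    "KTS": (("α1β1",), ("endothelial cells",)),
    "RTS": (("α1β1",), ("endothelial cells",)),
    "VGD": (("α5β1",), ("endothelial cells",)),
    "RED": (("αIIbβ3",), ("platelets",)),
}

DATABASE_COLUMNS = [
    "seq_id",
    "organism_code",
    "taxon_label",
    "tripeptide",
    "motif_start",
    "left_spacer",
    "right_spacer",
    "overlaps_signal",
    "integrin_targets",
    "cell_targets",
    "is_duodegrin",
    "sequence_length",
]


@dataclass(frozen=True)
class IntegrinAnnotation:
    tripeptide: str
    integrin_targets: tuple[str, ...]
    cell_targets: tuple[str, ...]
    provenance_note: str = ""


@dataclass(frozen=True)
class SequenceSummary:
    seq_id: str
    n_matches: int
    distinct_tripeptides: frozenset[str]
    is_duodegrin: bool


def load_annotation_table(path: str | Path) -> dict[str, tuple[tuple[str, ...], tuple[str, ...]]]:
    """Load a tripeptide->targets mapping from a YAML config.

    Format: ``{tripeptide: {integrins: [...], cells: [...]}}``.
    """
    with Path(path).open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    table = {}
    for tri, entry in raw.items():
        table[str(tri)] = (
            tuple(entry.get("integrins", [])),
            tuple(entry.get("cells", [])),
        )
    return table


def classify_match(
    match: MotifMatch,
    table: Mapping[str, tuple[tuple[str, ...], tuple[str, ...]]] = DEFAULT_ANNOTATION_TABLE,
) -> IntegrinAnnotation:
    """Putative integrin/cell targets for a match; unknown motifs unmapped."""
    if match.tripeptide in table:
        integrins, cells = table[match.tripeptide]
        return IntegrinAnnotation(match.tripeptide, integrins, cells)
    return IntegrinAnnotation(match.tripeptide, (), (), provenance_note="unmapped")


def summarize_sequence(matches: Sequence[MotifMatch]) -> SequenceSummary:
    """Per-sequence motif summary; all matches must share one seq_id."""
    ids = {m.seq_id for m in matches}
    if len(ids) > 1:
        raise ValueError(f"matches span multiple sequences: {sorted(ids)}")
    seq_id = matches[0].seq_id if matches else ""
    tris = frozenset(m.tripeptide for m in matches)
    return SequenceSummary(
        seq_id=seq_id,
        n_matches=len(matches),
        distinct_tripeptides=tris,
        is_duodegrin=len(matches) >= 2 and len(tris) >= 2,
    )


def build_database(
    table: MatchTable,
    records: Iterable[SequenceRecord],
    annotation_table: Mapping[str, tuple[tuple[str, ...], tuple[str, ...]]] = DEFAULT_ANNOTATION_TABLE,
) -> pd.DataFrame:
    """Assemble the motif-annotated sialogenin database, one row per match.

    Rows are sorted by (organism_code, seq_id, motif_start); integrin and
    cell target sets are serialized as comma-joined names in canonical
    order.
    """
    by_id = {r.id: r for r in records}
    summaries = {sid: summarize_sequence(ms) for sid, ms in table.by_sequence().items()}
    rows = []
    for m in table.matches:
        if m.seq_id not in by_id:
            raise KeyError(f"match references unknown sequence {m.seq_id!r}")
        rec = by_id[m.seq_id]
        ann = classify_match(m, annotation_table)
        rows.append(
            {
                "seq_id": m.seq_id,
                "organism_code": rec.organism_code,
                "taxon_label": rec.taxon_label,
                "tripeptide": m.tripeptide,
                "motif_start": m.motif_start,
                "left_spacer": m.left_spacer,
                "right_spacer": m.right_spacer,
                "overlaps_signal": m.overlaps_signal,
                "integrin_targets": ",".join(ann.integrin_targets),
                "cell_targets": ",".join(ann.cell_targets),
                "is_duodegrin": summaries[m.seq_id].is_duodegrin,
                "sequence_length": len(rec),
            }
        )
    df = pd.DataFrame(rows, columns=DATABASE_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["organism_code", "seq_id", "motif_start"], kind="mergesort"
        ).reset_index(drop=True)
    return df


def write_database_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write the database as UTF-8 TSV with booleans as ``true``/``false``."""
    out = df.copy()
    for col in ("overlaps_signal", "is_duodegrin"):
        if col in out.columns and len(out):
            out[col] = out[col].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_database_tsv(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_database_tsv` output."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8")
    for col in ("motif_start", "left_spacer", "right_spacer", "sequence_length"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    for col in ("overlaps_signal", "is_duodegrin"):
        if col in df.columns:
            df[col] = df[col].map({"true": True, "false": False})
    return df


def write_database_xlsx(df: pd.DataFrame, path: str | Path) -> None:
    """Optional worksheet export mirroring the TSV rows."""
    out = df.copy()
    out.to_excel(path, index=False, engine="openpyxl")
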