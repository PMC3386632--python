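"""Cysteine-flanked tripeptide motif scanning.

The search pattern is a PROSITE-style bounded-gap expression
``C-x(0,16)-X-Y-Z-x(0,16)-C``: a literal tripeptide (XYZ) with a cysteine
on each side separated by at most 16 intervening residues.  The default
tripeptide set covers the integrin-binding motifs of known disintegrins:
RGD, MLD, KGD, VGD, KTS, RTS, WGD and RED.

One match is emitted per tripeptide occurrence (never per cysteine pair);
when several cysteines qualify on a side, the innermost one is reported,
matching the picture of the motif presented at the apex of a loop
bracketed by cysteine residues.  Flanking cysteines must lie strictly
outside the tripeptide.  Matching is exact-literal, so an X (unknown
residue) in the sequence never matches a motif position.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .seqio import AMINO_ACIDS, SequenceRecord
from .signal import SignalPrediction

#: Tripeptide motifs of characterized disintegrin families.
DEFAULT_MOTIFS: tuple[str, ...] = ("RGD", "MLD", "KGD", "VGD", "KTS", "RTS", "WGD", "RED")

#: Maximum residues between a flanking cysteine and the tripeptide.
DEFAULT_MAX_SPACER = 16


class PatternError(ValueError):
    """Raised for an invalid motif pattern configuration."""


@dataclass(frozen=True)
class MotifPattern:
    """A literal tripeptide with bounded cysteine flanks."""

    tripeptide: str
    max_left_spacer: int = DEFAULT_MAX_SPACER
    max_right_spacer: int = DEFAULT_MAX_SPACER
    require_flanks: bool = True

    def __post_init__(self) -> None:
        if len(self.tripeptide) != 3:
            raise PatternError(f"tripeptide must have length 3: {self.tripeptide!r}")
        for ch in self.tripeptide:
            if ch not in AMINO_ACIDS:
                raise PatternError(
                    f"tripeptide {self.tripeptide!r}: {ch!r} is not a standard amino acid"
                )
        if self.max_left_spacer < 0 or self.max_right_spacer < 0:
            raise PatternError("spacer bounds must be >= 0")


def default_patterns(
    motifs: Sequence[str] = DEFAULT_MOTIFS,
    max_left_spacer: int = DEFAULT_MAX_SPACER,
    max_right_spacer: int = DEFAULT_MAX_SPACER,
) -> list[MotifPattern]:
    return [MotifPattern(m, max_left_spacer, max_right_spacer) for m in motifs]


@dataclass(frozen=True)
class MotifMatch:
    """One flanked tripeptide hit.  All coordinates are 1-based inclusive."""

    seq_id: str
    tripeptide: str
    motif_start: int
    left_cys_pos: int   # innermost qualifying cysteine; 0 when unflanked
    right_cys_pos: int
    left_spacer: int    # residues strictly between flank and motif; 0 when unflanked
    right_spacer: int
    overlaps_signal: bool = False

    @property
    def motif_end(self) -> int:
        return self.motif_start + 2


def _occurrences(residues: str, tripeptide: str) -> list[int]:
    """0-based start indices of every (possibly overlapping) occurrence."""
    hits = []
    i = residues.find(tripeptide)
    while i != -1:
        hits.append(i)
        i = residues.find(tripeptide, i + 1)
    return hits


def scan_sequence(
    record: SequenceRecord,
    patterns: Sequence[MotifPattern],
    signal: SignalPrediction | None = None,
) -> list[MotifMatch]:
    """Scan one record for every pattern; matches sorted by position.

    For each tripeptide occurrence a match is emitted iff a cysteine lies
    within the left spacer window and another within the right window
    (unless the pattern sets ``require_flanks=False``, in which case the
    occurrence is reported with zeroed flank fields when a side lacks a
    qualifying cysteine).  ``overlaps_signal`` is set when the motif starts
    at or before the predicted signal-peptide cleavage position.
    """
    if not patterns:
        raise PatternError("pattern set must be non-empty")
    seen = set()
    for p in patterns:
        if p.tripeptide in seen:
            raise PatternError(f"duplicate tripeptide in pattern set: {p.tripeptide}")
        seen.add(p.tripeptide)

    res = record.residues
    cys = [i + 1 for i, ch in enumerate(res) if ch == "C"]  # 1-based positions
    in_signal = signal is not None and signal.has_signal
    matches: list[MotifMatch] = []

    for pat in patterns:
        for idx in _occurrences(res, pat.tripeptide):
            m = idx + 1  # 1-based motif start
            # innermost left cysteine: largest p with m-1-max_left <= p <= m-1
            lo = m - 1 - pat.max_left_spacer
            k = bisect_right(cys, m - 1)
            left = cys[k - 1] if k > 0 and cys[k - 1] >= lo else 0
            # innermost right cysteine: smallest q with m+3 <= q <= m+3+max_right
            hi = m + 3 + pat.max_right_spacer
            k = bisect_left(cys, m + 3)
            right = cys[k] if k < len(cys) and cys[k] <= hi else 0
            if pat.require_flanks and (left == 0 or right == 0):
                continue
            matches.append(
                MotifMatch(
                    seq_id=record.id,
                    tripeptide=pat.tripeptide,
                    motif_start=m,
                    left_cys_pos=left,
                    right_cys_pos=right,
                    left_spacer=m - left - 1 if left else 0,
                    right_spacer=right - (m + 2) - 1 if right else 0,
                    overlaps_signal=in_signal and m <= signal.cleavage_pos,
                )
            )
    matches.sort(key=lambda mm: (mm.motif_start, mm.tripeptide))
    return matches


@dataclass
class MatchTable:
    """All matches of a record collection plus per-sequence counts."""

    matches: list[MotifMatch] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)  # seq_id -> n matches

    @property
    def n_matches(self) -> int:
        return len(self.matches)

    def by_sequence(self) -> dict[str, list[MotifMatch]]:
        out: dict[str, list[MotifMatch]] = {sid: [] for sid in self.counts}
        for m in self.matches:
            out[m.seq_id].append(m)
        return out


def scan_collection(
    records: Iterable[SequenceRecord],
    patterns: Sequence[MotifPattern],
    predictions: Mapping[str, SignalPrediction] | None = None,
) -> MatchTable:
    """Scan every record in order; records with zero matches appear in counts."""
    predictions = predictions or {}
    table = MatchTable()
    for rec in records:
        hits = scan_sequence(rec, patterns, predictions.get(rec.id))
        table.matches.extend(hits)
        table.counts[rec.id] = len(hits)
    return table
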