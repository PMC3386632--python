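"""Secretion gating via a transparent signal-peptide heuristic.

Candidate disintegrin precursors are retained only when they look secreted.
The heuristic mimics the classical tripartite signal-peptide architecture:

* an *n-region* — a positively charged start (initial Met or a Lys/Arg
  within the first 10 residues);
* an *h-region* — a run of at least 8 consecutive hydrophobic residues
  (A, I, L, M, F, V, W) within the first 30 positions;
* a cleavage site located by the von-Heijne-style (-3, -1) rule: the
  residues three and one positions before the cut must both be small
  (A, G, S, C, T), searched up to position 45.

Externally computed predictions (e.g. from a dedicated signal-peptide
server) can be imported from TSV and take precedence over the heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .seqio import SequenceRecord

HYDROPHOBIC = frozenset("AILMFVW")
SMALL_RESIDUES = frozenset("AGSCT")
POSITIVE = frozenset("KR")


@dataclass(frozen=True)
class GateParams:
    """Tunable thresholds of the secretion heuristic."""

    n_region_window: int = 10   # residues searched for the charged start
    h_region_window: int = 30   # residues in which the hydrophobic run must sit
    min_h_run: int = 8          # minimum hydrophobic run length
    max_cleavage: int = 45      # signal peptides longer than this are not considered


@dataclass(frozen=True)
class SignalPrediction:
    seq_id: str
    has_signal: bool
    cleavage_pos: int  # 1-based last residue of the signal peptide; 0 if none
    score: float       # in [0, 1]

    def __post_init__(self) -> None:
        if not self.has_signal and self.cleavage_pos != 0:
            raise ValueError(
                f"{self.seq_id}: cleavage_pos must be 0 without a signal peptide"
            )


def _first_hydrophobic_run(residues: str, params: GateParams) -> tuple[int, int] | None:
    """First maximal hydrophobic run overlapping the h-window by >= min_h_run.

    Returns 1-based (start, end) of the full run, or None.
    """
    n = len(residues)
    i = 0
    while i < n:
        if residues[i] in HYDROPHOBIC:
            j = i
            while j < n and residues[j] in HYDROPHOBIC:
                j += 1
            # overlap of [i, j) with the window [0, h_region_window)
            overlap = min(j, params.h_region_window) - i
            if overlap >= params.min_h_run and i < params.h_region_window:
                return i + 1, j
            i = j
        else:
            i += 1
    return None


def predict_signal(record: SequenceRecord, params: GateParams = GateParams()) -> SignalPrediction:
    """Deterministic secretion verdict for one record.

    Sequences shorter than 15 residues are reported non-secreted with score
    0 rather than raising.
    """
    res = record.residues
    if len(res) < 15:
        return SignalPrediction(record.id, False, 0, 0.0)

    n_ok = res[0] == "M" or any(c in POSITIVE for c in res[: params.n_region_window])
    run = _first_hydrophobic_run(res, params)
    if not n_ok or run is None:
        return SignalPrediction(record.id, False, 0, 0.0)

    h_start, h_end = run
    cap = min(params.max_cleavage, len(res) - 1)
    cleavage = 0
    for pos in range(max(h_end + 1, 3), cap + 1):
        if res[pos - 3] in SMALL_RESIDUES and res[pos - 1] in SMALL_RESIDUES:
            cleavage = pos
            break
    if cleavage == 0:
        cleavage = min(h_end + 5, cap)
    score = min((h_end - h_start + 1) / params.h_region_window, 1.0)
    return SignalPrediction(record.id, True, cleavage, round(score, 6))


def load_external_predictions(path: str | Path) -> dict[str, SignalPrediction]:
    """Load a TSV of externally computed predictions.

    Expected columns (header row required): ``seq_id``, ``has_signal`` (Y/N),
    ``cleavage_pos``, ``score``.  Rows with ``has_signal`` N force the
    cleavage position to 0 regardless of the column value.
    """
    path = Path(path)
    out: dict[str, SignalPrediction] = {}
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
        cols = [c.strip() for c in header.rstrip("\n").split("\t")]
        required = ["seq_id", "has_signal", "cleavage_pos", "score"]
        if cols[: len(required)] != required:
            raise ValueError(
                f"{path}: expected header columns {required}, got {cols}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: malformed row ({len(parts)} fields)")
            seq_id, flag, cleav, score = parts[0], parts[1], parts[2], parts[3]
            if seq_id in out:
                raise ValueError(f"{path}:{lineno}: duplicate seq_id {seq_id!r}")
            if flag not in ("Y", "N"):
                raise ValueError(f"{path}:{lineno}: has_signal must be Y or N, got {flag!r}")
            try:
                cleavage = int(cleav)
                sc = float(score)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            has = flag == "Y"
            out[seq_id] = SignalPrediction(seq_id, has, cleavage if has else 0, sc)
    return out


def filter_secreted(
    records: Iterable[SequenceRecord],
    predictions: Mapping[str, SignalPrediction] | None = None,
    policy: str = "require",
    params: GateParams = GateParams(),
) -> tuple[list[SequenceRecord], list[tuple[str, str]], dict[str, SignalPrediction]]:
    """Apply the secretion gate.

    ``policy`` is ``"require"`` (drop records without a signal peptide) or
    ``"annotate"`` (keep everything, verdicts carried alongside).  External
    predictions take precedence over the heuristic.  Returns the kept
    records, a drop log of ``(seq_id, reason)`` pairs, and the resolved
    prediction for every input record.
    """
    if policy not in ("require", "annotate"):
        raise ValueError(f"unknown signal policy {policy!r}")
    predictions = predictions or {}
    kept: list[SequenceRecord] = []
    dropped: list[tuple[str, str]] = []
    resolved: dict[str, SignalPrediction] = {}
    for rec in records:
        if rec.id in predictions:
            pred = predictions[rec.id]
            source = "external"
        else:
            pred = predict_signal(rec, params)
            source = "heuristic"
        resolved[rec.id] = pred
        if policy == "annotate" or pred.has_signal:
            kept.append(rec)
        else:
            dropped.append((rec.id, f"no signal peptide ({source}, score={pred.score:g})"))
    return kept, dropped, resolved
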