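"""End-to-end disintegrin discovery pipeline.

Stage order is fixed: load FASTA → taxon scoping → secretion gate → motif
scan → annotation/summary → outputs.  Taxon scoping is metadata matching
against the record's taxon label, description, or organism code — no live
retrieval.  All output sorting and number formats are pinned so repeated
runs with identical config and inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import annotate as ann
from .motifs import DEFAULT_MAX_SPACER, DEFAULT_MOTIFS, MatchTable, default_patterns, scan_collection
from .seqio import SequenceRecord, read_fasta, write_fasta
from .signal import GateParams, filter_secreted, load_external_predictions
from .simulate import DEFAULT_TAXA, generate_proteome, write_fixture


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``taxon_allowlist`` defaults to the eleven blood-feeding taxa searched
    for salivary disintegrin candidates; an empty list keeps every record.
    """

    inputs: list[str] = field(default_factory=list)
    motifs: list[str] = field(default_factory=lambda: list(DEFAULT_MOTIFS))
    max_left_spacer: int = DEFAULT_MAX_SPACER
    max_right_spacer: int = DEFAULT_MAX_SPACER
    taxon_allowlist: list[str] = field(default_factory=lambda: list(DEFAULT_TAXA))
    signal_policy: str = "require"  # require | annotate
    external_predictions: str | None = None
    annotation_table: str | None = None
    seed: int = 0
    outdir: str = "degrinscan_out"

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("motif set must be non-empty")
        if self.max_left_spacer < 0 or self.max_right_spacer < 0:
            raise ValueError("spacer bounds must be >= 0")
        if self.signal_policy not in ("require", "annotate"):
            raise ValueError(f"unknown signal policy {self.signal_policy!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    config: RunConfig
    database: pd.DataFrame
    counts: dict[str, int]
    drop_log: list[tuple[str, str, str]]  # (stage, seq_id, reason)
    outdir: Path


def _matches_taxon(rec: SequenceRecord, allowlist: Sequence[str]) -> bool:
    if not allowlist:
        return True
    haystack = f"{rec.taxon_label} {rec.description}".lower()
    for term in allowlist:
        if term.lower() in haystack:
            return True
        if rec.organism_code and rec.organism_code == term[:5].upper():
            return True
    return False


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full flow and write the output bundle.

    Outputs under ``config.outdir``: ``database.tsv`` (one row per motif
    match), ``motif_<XYZ>.fasta`` per configured motif (records carrying at
    least one match of that motif), ``summary.txt`` (stage counts + config
    echo) and ``drop_log.tsv``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    drop_log: list[tuple[str, str, str]] = []

    # load
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for path in config.inputs:
        for rec in read_fasta(path):
            if rec.id in seen:
                raise ValueError(f"duplicate identifier {rec.id!r} across input files")
            seen.add(rec.id)
            records.append(rec)
    n_loaded = len(records)

    # taxon scoping
    scoped = []
    for rec in records:
        if _matches_taxon(rec, config.taxon_allowlist):
            scoped.append(rec)
        else:
            drop_log.append(("taxon", rec.id, "no allow-list term matched"))
    n_taxon = len(scoped)

    # secretion gate
    external = (
        load_external_predictions(config.external_predictions)
        if config.external_predictions
        else None
    )
    kept, gate_drops, predictions = filter_secreted(
        scoped, external, policy=config.signal_policy, params=GateParams()
    )
    drop_log.extend(("signal", sid, reason) for sid, reason in gate_drops)
    n_secreted = sum(1 for r in kept if predictions[r.id].has_signal)

    # scan
    patterns = default_patterns(
        config.motifs, config.max_left_spacer, config.max_right_spacer
    )
    table = scan_collection(kept, patterns, predictions)

    # annotate + database
    annotation_table = (
        ann.load_annotation_table(config.annotation_table)
        if config.annotation_table
        else ann.DEFAULT_ANNOTATION_TABLE
    )
    db = ann.build_database(table, kept, annotation_table)
    ann.write_database_tsv(db, outdir / "database.tsv")

    # per-motif FASTA subsets
    matched_by_motif: dict[str, list[str]] = {m: [] for m in config.motifs}
    for match in table.matches:
        ids = matched_by_motif[match.tripeptide]
        if match.seq_id not in ids:
            ids.append(match.seq_id)
    rec_by_id = {r.id: r for r in kept}
    for motif in config.motifs:
        subset = [rec_by_id[sid] for sid in matched_by_motif[motif]]
        write_fasta(subset, outdir / f"motif_{motif}.fasta")

    n_dup = int(db.loc[db["is_duodegrin"], "seq_id"].nunique()) if len(db) else 0
    counts = {
        "loaded": n_loaded,
        "taxon_kept": n_taxon,
        "secreted": n_secreted,
        "matched_sequences": sum(1 for c in table.counts.values() if c),
        "total_matches": table.n_matches,
        "duodegrins": n_dup,
    }

    with (outdir / "drop_log.tsv").open("w", encoding="utf-8") as fh:
        fh.write("stage\tseq_id\treason\n")
        for stage, sid, reason in drop_log:
            fh.write(f"{stage}\t{sid}\t{reason}\n")

    with (outdir / "summary.txt").open("w", encoding="utf-8") as fh:
        fh.write("degrinscan pipeline summary\n")
        for key in ("loaded", "taxon_kept", "secreted", "matched_sequences",
                    "total_matches", "duodegrins"):
            fh.write(f"{key}\t{counts[key]}\n")
        fh.write("\n# configuration\n")
        fh.write(yaml.safe_dump(config.to_dict(), sort_keys=True))

    return PipelineResult(config, db, counts, drop_log, outdir)


@dataclass
class SelfTestReport:
    passed: bool
    details: list[str]
    counts: dict[str, int]


def selftest(seed: int = 0, workdir: str | Path | None = None, n: int = 60) -> SelfTestReport:
    """Generate a ledger-audited fixture, run the pipeline, check agreement.

    The pipeline's database rows must exactly equal the ledger's detectable
    entries restricted to secreted records (the default policy drops the
    rest), and every planted VGD+RTS pair must be flagged as a duodegrin.
    """
    import tempfile

    details: list[str] = []
    records, ledger = generate_proteome(n=n, seed=seed)
    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    base = Path(ctx.name) if ctx else Path(workdir)
    try:
        fasta, _ = write_fixture(records, ledger, base)
        config = RunConfig(inputs=[str(fasta)], seed=seed, outdir=str(base / "out"))
        result = run_pipeline(config)

        secreted = ledger.secreted_ids()
        expected = {
            (e.seq_id, e.tripeptide, e.motif_start)
            for e in ledger.motif_entries(detectable=True)
            if e.seq_id in secreted
        }
        observed = {
            (row.seq_id, row.tripeptide, int(row.motif_start))
            for row in result.database.itertuples()
        }
        missing = expected - observed
        extra = observed - expected
        if missing:
            details.append(f"{len(missing)} ledger entries not recovered: {sorted(missing)[:5]}")
        if extra:
            details.append(f"{len(extra)} unexpected database rows: {sorted(extra)[:5]}")

        # duodegrin agreement from the ledger itself
        per_seq: dict[str, set[str]] = {}
        for e in ledger.motif_entries(detectable=True):
            if e.seq_id in secreted:
                per_seq.setdefault(e.seq_id, set()).add(e.tripeptide)
        expected_dup = {sid for sid, tris in per_seq.items() if len(tris) >= 2}
        db = result.database
        observed_dup = set(db[db["is_duodegrin"]]["seq_id"]) if len(db) else set()
        if expected_dup != observed_dup:
            details.append(
                f"duodegrin mismatch: expected {sorted(expected_dup)}, got {sorted(observed_dup)}"
            )
        return SelfTestReport(passed=not details, details=details, counts=result.counts)
    finally:
        if ctx:
            ctx.cleanup()
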