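"""Synthetic proteomes and alignments with known ground truth.

No public corpus ships with this package; instead every pipeline stage is
exercised against generated data whose expected outcome is recorded in a
plant ledger:

* secreted records receive an N-terminal segment built to satisfy the
  secretion heuristic exactly (charged start, hydrophobic core, small
  residues at the -3/-1 cleavage positions); non-secreted records have any
  would-be hydrophobic core broken so the gate must reject them;
* motif plants insert ``C + spacer + tripeptide + spacer + C`` segments
  with spacers drawn uniformly from [0, 16] and cysteine-free fillers, so
  the planted cysteines are the innermost flanks;
* decoys probe the pattern boundaries: a motif with no cysteine within the
  right window, a motif with a spacer of exactly 17, and a motif placed
  inside the signal-peptide region (detected, but flagged as overlapping
  the signal).

After assembly the proteome is audited: the scanner is run and any
accidental motif occurrence with qualifying flanks (arising from the
random background) is appended to the ledger, so fixture-based counts are
exact rather than probabilistic.  A mismatch between the audit and the
planted expectations is a construction error and raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .motifs import DEFAULT_MOTIFS, default_patterns, scan_collection
from .seqio import AMINO_ACIDS, SequenceRecord, write_fasta
from .signal import GateParams, predict_signal
from .phylo import Alignment, DistanceMatrix, PhyloTree, TreeNode

#: Taxa searched for salivary disintegrin candidates (ticks, bugs,
#: tabanids, tsetse, mosquitoes, sand flies, black flies, midges, fleas,
#: leeches, nematodes).
DEFAULT_TAXA: tuple[str, ...] = (
    "Ixodoidea",
    "Cimicomorpha",
    "Tabanidae",
    "Glossina",
    "Culicidae",
    "Psychodidae",
    "Simuliidae",
    "Ceratopogonidae",
    "Siphonaptera",
    "Hirudinea",
    "Rhabditida",
)

_NON_CYS = AMINO_ACIDS.replace("C", "")
_HYDRO = "LVIF"  # used for planted h-regions

LEDGER_COLUMNS = [
    "seq_id",
    "kind",
    "tripeptide",
    "motif_start",
    "left_spacer",
    "right_spacer",
    "expected_detection",
    "planted",
]


@dataclass
class PlantEntry:
    """One ledger line: a planted (or audited accidental) item."""

    seq_id: str
    kind: str  # motif | signal | decoy
    tripeptide: str = ""
    motif_start: int = 0
    left_spacer: int = -1
    right_spacer: int = -1
    expected_detection: bool = False
    planted: bool = True


@dataclass
class PlantLedger:
    entries: list[PlantEntry] = field(default_factory=list)

    def motif_entries(self, detectable: bool | None = None) -> list[PlantEntry]:
        out = [e for e in self.entries if e.kind in ("motif", "decoy") and e.tripeptide]
        if detectable is not None:
            out = [e for e in out if e.expected_detection == detectable]
        return out

    def secreted_ids(self) -> set[str]:
        return {
            e.seq_id
            for e in self.entries
            if e.kind == "signal" and e.expected_detection
        }

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("\t".join(LEDGER_COLUMNS) + "\n")
            for e in self.entries:
                fh.write(
                    "\t".join(
                        [
                            e.seq_id,
                            e.kind,
                            e.tripeptide,
                            str(e.motif_start),
                            str(e.left_spacer),
                            str(e.right_spacer),
                            "true" if e.expected_detection else "false",
                            "true" if e.planted else "false",
                        ]
                    )
                    + "\n"
                )


def _background(rng: np.random.Generator, length: int, cys_weight: float) -> str:
    weights = np.full(20, (1.0 - cys_weight) / 19)
    weights[AMINO_ACIDS.index("C")] = cys_weight
    letters = rng.choice(list(AMINO_ACIDS), size=length, p=weights)
    return "".join(letters)


def _non_cys_fill(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_NON_CYS), size=length)) if length else ""


def _break_hydrophobic_runs(seq: str, window: int, max_run: int) -> str:
    """Interrupt hydrophobic runs in the first ``window`` residues.

    Guarantees no run of length > max_run survives there, so the secretion
    heuristic must reject the record.
    """
    from .signal import HYDROPHOBIC

    chars = list(seq)
    run = 0
    for i in range(min(window, len(chars))):
        if chars[i] in HYDROPHOBIC:
            run += 1
            if run > max_run:
                chars[i] = "G"
                run = 0
        else:
            run = 0
    return "".join(chars)


def _signal_prefix(rng: np.random.Generator) -> str:
    """An N-terminal segment the secretion heuristic must accept."""
    h_len = int(rng.integers(8, 13))
    core = "".join(rng.choice(list(_HYDRO), size=h_len))
    return "M" + str(rng.choice(["K", "R"])) + core + "ASA"


def _signal_prefix_with_motif(rng: np.random.Generator, tripeptide: str) -> tuple[str, int]:
    """A secretion-positive prefix carrying a flanked motif inside it.

    Returns (prefix, 1-based motif start).  The hydrophobic core ends at
    position 10, so the cleavage-site search cannot resolve before the
    motif begins at position 12; the motif therefore always overlaps the
    predicted signal peptide.
    """
    prefix = "MK" + "L" * 8 + "C" + tripeptide + "C" + "ASA"
    return prefix, 12


@dataclass
class _Insert:
    segment: str
    kind: str  # motif | no_flank | spacer17
    tripeptide: str
    motif_offset: int  # 0-based offset of the tripeptide within segment
    left_spacer: int
    right_spacer: int
    expected: bool


def _motif_insert(rng: np.random.Generator, tripeptide: str) -> _Insert:
    ls = int(rng.integers(0, 17))
    rs = int(rng.integers(0, 17))
    seg = "C" + _non_cys_fill(rng, ls) + tripeptide + _non_cys_fill(rng, rs) + "C"
    return _Insert(seg, "motif", tripeptide, 1 + ls, ls, rs, True)


def _no_flank_insert(rng: np.random.Generator, tripeptide: str) -> _Insert:
    # valid left flank; the entire 17-residue right window is cysteine-free
    ls = int(rng.integers(0, 17))
    seg = "C" + _non_cys_fill(rng, ls) + tripeptide + _non_cys_fill(rng, 17)
    return _Insert(seg, "no_flank", tripeptide, 1 + ls, ls, -1, False)


def _spacer17_insert(rng: np.random.Generator, tripeptide: str) -> _Insert:
    # left spacer exactly one beyond the bound; right flank valid
    rs = int(rng.integers(0, 17))
    seg = "C" + _non_cys_fill(rng, 17) + tripeptide + _non_cys_fill(rng, rs) + "C"
    return _Insert(seg, "spacer17", tripeptide, 18, 17, rs, False)


def generate_proteome(
    n: int = 200,
    length_range: tuple[int, int] = (80, 300),
    motif_density: float = 0.8,
    signal_fraction: float = 0.6,
    decoy_mix: dict[str, float] | None = None,
    cys_weight: float = 0.05,
    motifs: Sequence[str] = DEFAULT_MOTIFS,
    seed: int = 0,
    duodegrin_pairs: int = 2,
) -> tuple[list[SequenceRecord], PlantLedger]:
    """Generate a proteome with planted signals, motifs and decoys.

    The number of motif plants per record is Poisson(``motif_density``);
    decoy probabilities per record come from ``decoy_mix`` (defaults:
    no_flank 0.10, spacer17 0.10, in_signal 0.05).  The first
    ``duodegrin_pairs`` secreted records carry a planted VGD + RTS pair so
    duodegrin flagging is always exercised.  Deterministic under ``seed``.
    """
    if decoy_mix is None:
        decoy_mix = {"no_flank": 0.10, "spacer17": 0.10, "in_signal": 0.05}
    lo, hi = length_range
    if lo < 60:
        raise ValueError("length_range minimum must be >= 60 to fit plants and spacers")
    rng = np.random.default_rng(seed)
    params = GateParams()

    records: list[SequenceRecord] = []
    ledger = PlantLedger()
    duode_left = duodegrin_pairs

    for i in range(n):
        taxon = DEFAULT_TAXA[int(rng.integers(0, len(DEFAULT_TAXA)))]
        code = taxon[:5].upper()
        seq_id = f"{code}_{100000 + i}"
        secreted = bool(rng.random() < signal_fraction)

        inserts: list[_Insert] = []
        in_signal_decoy = secreted and rng.random() < decoy_mix.get("in_signal", 0.0)

        if duode_left > 0 and secreted and not in_signal_decoy:
            inserts.append(_motif_insert(rng, "VGD"))
            inserts.append(_motif_insert(rng, "RTS"))
            duode_left -= 1
        else:
            for _ in range(int(rng.poisson(motif_density))):
                tri = str(rng.choice(list(motifs)))
                inserts.append(_motif_insert(rng, tri))
        if rng.random() < decoy_mix.get("no_flank", 0.0):
            inserts.append(_no_flank_insert(rng, str(rng.choice(list(motifs)))))
        if rng.random() < decoy_mix.get("spacer17", 0.0):
            inserts.append(_spacer17_insert(rng, str(rng.choice(list(motifs)))))

        if in_signal_decoy:
            tri = str(rng.choice(list(motifs)))
            prefix, sig_motif_start = _signal_prefix_with_motif(rng, tri)
        elif secreted:
            prefix = _signal_prefix(rng)
            sig_motif_start = 0
        else:
            prefix = ""
            sig_motif_start = 0

        body_len = int(rng.integers(lo, hi + 1))
        body = _background(rng, body_len, cys_weight)
        if not secreted:
            body = _break_hydrophobic_runs(body, params.h_region_window, params.min_h_run - 1)

        # splice inserts into the body at sorted random cut points; in
        # non-secreted records the broken-run prefix of the body must stay
        # intact, so inserts (whose fillers may be hydrophobic) go after it
        min_cut = 0 if secreted else params.h_region_window
        cuts = sorted(int(rng.integers(min_cut, body_len + 1)) for _ in inserts)
        seq_parts: list[str] = [prefix]
        pos = len(prefix)  # residues emitted so far
        prev = 0
        placed: list[tuple[_Insert, int]] = []  # (insert, 1-based motif start)
        for ins, cut in zip(inserts, cuts):
            seq_parts.append(body[prev:cut])
            pos += cut - prev
            placed.append((ins, pos + ins.motif_offset + 1))
            seq_parts.append(ins.segment)
            pos += len(ins.segment)
            prev = cut
        seq_parts.append(body[prev:])
        residues = "".join(seq_parts)

        rec = SequenceRecord(
            id=seq_id,
            residues=residues,
            organism_code=code,
            taxon_label=taxon,
            description=f"{taxon} synthetic salivary protein {i}",
        )
        rec.validate()
        records.append(rec)

        pred = predict_signal(rec, params)
        if secreted and not pred.has_signal:
            raise RuntimeError(f"{seq_id}: planted signal peptide not recognized")
        if not secreted and pred.has_signal:
            raise RuntimeError(f"{seq_id}: non-secreted record passes the gate")
        ledger.entries.append(
            PlantEntry(seq_id, "signal", expected_detection=secreted)
        )
        if in_signal_decoy:
            ledger.entries.append(
                PlantEntry(
                    seq_id,
                    "decoy",
                    tripeptide=tri,
                    motif_start=sig_motif_start,
                    left_spacer=0,
                    right_spacer=0,
                    expected_detection=True,
                )
            )
        for ins, start in placed:
            ledger.entries.append(
                PlantEntry(
                    seq_id,
                    "motif" if ins.kind == "motif" else "decoy",
                    tripeptide=ins.tripeptide,
                    motif_start=start,
                    left_spacer=ins.left_spacer,
                    right_spacer=ins.right_spacer,
                    expected_detection=ins.expected,
                )
            )

    _audit(records, ledger, motifs)
    return records, ledger


def _audit(
    records: list[SequenceRecord],
    ledger: PlantLedger,
    motifs: Sequence[str],
) -> None:
    """Reconcile scanner output with the planted expectations.

    Every planted expected-true entry must be found at its recorded
    coordinates; every expected-false entry must be absent; any extra hit
    is recorded as an unplanted (accidental) motif so ledger counts are
    exact.  Violations raise RuntimeError — they indicate a generator bug,
    not bad luck.
    """
    table = scan_collection(records, default_patterns(motifs))
    found = {(m.seq_id, m.tripeptide, m.motif_start): m for m in table.matches}
    for e in ledger.motif_entries():
        key = (e.seq_id, e.tripeptide, e.motif_start)
        if e.expected_detection and key not in found:
            raise RuntimeError(f"planted motif not detected: {key}")
        if not e.expected_detection and key in found:
            raise RuntimeError(f"decoy unexpectedly detected: {key}")
    planted_keys = {
        (e.seq_id, e.tripeptide, e.motif_start)
        for e in ledger.motif_entries(detectable=True)
    }
    for key, m in sorted(found.items()):
        if key not in planted_keys:
            ledger.entries.append(
                PlantEntry(
                    m.seq_id,
                    "motif",
                    tripeptide=m.tripeptide,
                    motif_start=m.motif_start,
                    left_spacer=m.left_spacer,
                    right_spacer=m.right_spacer,
                    expected_detection=True,
                    planted=False,
                )
            )


def write_fixture(
    records: list[SequenceRecord],
    ledger: PlantLedger,
    outdir: str | Path,
    basename: str = "fixture",
) -> tuple[Path, Path]:
    """Write the proteome FASTA and the ledger TSV; returns both paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{basename}.fasta"
    tsv = outdir / f"{basename}.ledger.tsv"
    write_fasta(records, fasta)
    ledger.write_tsv(tsv)
    return fasta, tsv


def generate_alignment_fixture(
    tree_spec: dict,
    n_cols: int = 100,
    seed: int = 0,
) -> Alignment:
    """Build an alignment whose columns support prescribed bipartitions.

    ``tree_spec`` is ``{"taxa": [...], "splits": [(side_taxa, k), ...]}``:
    each listed split contributes ``k`` columns in which the taxa on one
    side share one residue and the rest share another.  Remaining columns
    are constant.  Column order is shuffled (seeded).
    """
    taxa: list[str] = list(tree_spec["taxa"])
    rng = np.random.default_rng(seed)
    columns: list[dict[str, str]] = []
    residue_pool = list(_NON_CYS)
    for side, k in tree_spec.get("splits", []):
        side = set(side)
        unknown = side - set(taxa)
        if unknown:
            raise ValueError(f"split names unknown taxa: {sorted(unknown)}")
        for _ in range(int(k)):
            r1, r2 = rng.choice(residue_pool, size=2, replace=False)
            columns.append({t: (r1 if t in side else r2) for t in taxa})
    while len(columns) < n_cols:
        columns.append({t: "A" for t in taxa})
    if len(columns) > n_cols:
        raise ValueError("split columns exceed n_cols")
    order = rng.permutation(len(columns))
    rows = ["".join(columns[j][t] for j in order) for t in taxa]
    return Alignment(taxa, rows)


def random_binary_tree(
    n_leaves: int,
    rng: np.random.Generator,
    length_range: tuple[float, float] = (0.01, 0.5),
) -> PhyloTree:
    """A random unrooted binary topology with uniform branch lengths.

    Built by sequential addition: each new leaf splits a uniformly chosen
    existing edge.  Used to test distance-based tree reconstruction on
    additive matrices.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    lo, hi = length_range

    def blen() -> float:
        return float(rng.uniform(lo, hi))

    names = [f"t{i}" for i in range(n_leaves)]
    root = TreeNode()
    for nm in names[:3]:
        leaf = TreeNode(name=nm)
        leaf.length = leaf.raw_length = blen()
        root.children.append(leaf)

    def edges(node: TreeNode) -> list[tuple[TreeNode, TreeNode]]:
        out = []
        for ch in node.children:
            out.append((node, ch))
            out.extend(edges(ch))
        return out

    for nm in names[3:]:
        parent, child = edges(root)[int(rng.integers(0, len(edges(root))))]
        mid = TreeNode()
        half = child.length / 2
        mid.length = mid.raw_length = half
        child.length = child.raw_length = child.length - half
        parent.children[parent.children.index(child)] = mid
        leaf = TreeNode(name=nm)
        leaf.length = leaf.raw_length = blen()
        mid.children = [child, leaf]
    return PhyloTree(root)


def distance_matrix_from_tree(tree: PhyloTree) -> DistanceMatrix:
    """Additive leaf-to-leaf path-length matrix of a tree."""
    paths = tree.path_lengths()
    ids = sorted(tree.leaf_names())
    n = len(ids)
    d = np.zeros((n, n))
    for (a, b), dist in paths.items():
        i, j = ids.index(a), ids.index(b)
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(ids, d)
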