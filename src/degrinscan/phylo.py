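"""Family phylograms: p-distances, neighbor-joining, bootstrap supports.

Putative disintegrin families are summarized as unrooted neighbor-joining
phylograms built from uncorrected p-distances (proportion of mismatched
residues over gap-free compared columns, i.e. pairwise deletion).  Branch
support is estimated by the nonparametric bootstrap: alignment columns are
resampled with replacement, a tree is built per replicate, and each
internal bipartition of the full-data tree is annotated with the
percentage of replicates containing it.

Multiple alignments are consumed (aligned FASTA or Clustal format), never
computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import AlignIO, SeqIO

from .seqio import FastaError

GAP = "-"


@dataclass
class Alignment:
    """A multiple protein alignment: equal-length rows over residues + '-'."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids are not unique")
        if self.rows:
            n = len(self.rows[0])
            for ident, row in zip(self.ids, self.rows):
                if len(row) != n:
                    raise ValueError(
                        f"ragged alignment: row {ident!r} has length {len(row)}, expected {n}"
                    )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, column_idx: Sequence[int]) -> "Alignment":
        rows = ["".join(row[j] for j in column_idx) for row in self.rows]
        return Alignment(list(self.ids), rows)


def read_alignment(path: str | Path, fmt: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Clustal file; rows case-normalized to upper."""
    path = Path(path)
    if fmt == "fasta":
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
    elif fmt == "clustal":
        aln = AlignIO.read(str(path), "clustal")
        ids = [rec.id for rec in aln]
        rows = [str(rec.seq).upper() for rec in aln]
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
    if not ids:
        raise FastaError(f"{path}: no alignment rows found")
    return Alignment(ids, rows)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n},{n})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")


def p_distance(alignment: Alignment) -> DistanceMatrix:
    """Uncorrected pairwise p-distance with pairwise gap deletion.

    d(i,j) = mismatches / compared sites over columns where neither row has
    a gap.  A pair with zero comparable columns is an error.
    """
    if alignment.n_rows < 2:
        raise ValueError("p_distance needs at least 2 rows")
    arr = np.array([list(r) for r in alignment.rows])
    gap = arr == GAP
    n = alignment.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            sites = int(ok.sum())
            if sites == 0:
                raise ValueError(
                    f"no comparable columns between {alignment.ids[i]!r} "
                    f"and {alignment.ids[j]!r}"
                )
            mism = int((arr[i, ok] != arr[j, ok]).sum())
            d[i, j] = d[j, i] = mism / sites
    return DistanceMatrix(list(alignment.ids), d)


@dataclass
class TreeNode:
    """Node of an unrooted tree stored with a top-level trifurcation."""

    name: str = ""  # non-empty for leaves
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0       # branch to parent; raw (pre-clamp) kept separately
    raw_length: float = 0.0
    support: int | None = None  # percent bootstrap support on the edge above

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for ch in self.children:
            yield from ch.walk()

    def leaf_names(self) -> frozenset[str]:
        return frozenset(n.name for n in self.walk() if n.is_leaf)


@dataclass
class PhyloTree:
    """Unrooted phylogram; root is an arbitrary internal trifurcation."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Internal-edge splits as the leaf set on the child side.

        Only informative edges (>= 2 leaves on each side) are returned,
        keyed by the child-side leaf set, mapped to the child node whose
        parent edge realizes the split.
        """
        all_leaves = self.leaf_names()
        out: dict[frozenset[str], TreeNode] = {}
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = node.leaf_names()
            if len(side) >= 2 and len(all_leaves - side) >= 2:
                out[side] = node
        return out

    def splits(self) -> set[frozenset[frozenset[str]]]:
        """Unordered bipartitions, orientation-free (for comparing trees)."""
        all_leaves = self.leaf_names()
        return {
            frozenset((side, all_leaves - side)) for side in self.bipartitions()
        }

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths along branch lengths."""
        # depth of every node from the root, then distance via shared path
        adj: dict[int, list[tuple[int, float]]] = {}
        names: dict[int, str] = {}

        def build(node: TreeNode) -> None:
            adj.setdefault(id(node), [])
            if node.is_leaf:
                names[id(node)] = node.name
            for ch in node.children:
                adj.setdefault(id(ch), [])
                adj[id(node)].append((id(ch), ch.length))
                adj[id(ch)].append((id(node), ch.length))
                build(ch)

        build(self.root)
        out: dict[tuple[str, str], float] = {}
        for start, sname in names.items():
            dist = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for other, oname in names.items():
                if oname > sname:
                    out[(sname, oname)] = dist[other]
        return out


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing Q(i,j) = (n-2) d(i,j) - R_i - R_j is
    joined; ties are broken by the smallest (i, j) index pair in current
    order.  Negative branch lengths are clamped to 0 after computation
    (raw values retained on each node).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=ident) for ident in dm.ids]
    d = dm.d.astype(float).copy()

    def set_length(node: TreeNode, raw: float) -> None:
        node.raw_length = raw
        node.length = max(raw, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        set_length(nodes[i], li)
        set_length(nodes[j], lj)
        # distances from the new node to every remaining node
        keep = [k for k in range(m) if k not in (i, j)]
        new_row = 0.5 * (d[i, keep] + d[j, keep] - d[i, j])
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row
        d[:-1, -1] = new_row
        nodes = [nodes[k] for k in keep] + [parent]

    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    set_length(a, 0.5 * (dab + dac - dbc))
    set_length(b, 0.5 * (dab + dbc - dac))
    set_length(c, 0.5 * (dac + dbc - dab))
    return PhyloTree(TreeNode(children=[a, b, c]))


def bootstrap_support(
    alignment: Alignment,
    replicates: int = 1000,
    seed: int = 0,
) -> tuple[PhyloTree, dict]:
    """NJ tree on the full alignment with percent bootstrap supports.

    ``replicates`` pseudo-alignments are drawn by sampling n_cols columns
    with replacement (seeded); the support of each internal bipartition of
    the full-data tree is the rounded percentage of replicate trees
    containing it.  A replicate whose resampled columns leave some pair
    with zero comparable sites is resampled (counted in the returned log).
    """
    if replicates < 1:
        raise ValueError("need at least 1 bootstrap replicate")
    tree = neighbor_joining(p_distance(alignment))
    biparts = tree.bipartitions()
    all_leaves = tree.leaf_names()
    split_keys = {
        side: frozenset((side, all_leaves - side)) for side in biparts
    }
    counts = {key: 0 for key in split_keys.values()}

    rng = np.random.default_rng(seed)
    resampled = 0
    done = 0
    max_attempts = 100 * replicates + 100
    attempts = 0
    while done < replicates:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("bootstrap: too many degenerate replicates")
        idx = rng.integers(0, alignment.n_cols, size=alignment.n_cols)
        pseudo = alignment.resample_columns(idx.tolist())
        try:
            rep_tree = neighbor_joining(p_distance(pseudo))
        except ValueError:
            resampled += 1
            continue
        rep_splits = rep_tree.splits()
        for key in counts:
            if key in rep_splits:
                counts[key] += 1
        done += 1

    for side, node in biparts.items():
        node.support = int(round(100 * counts[split_keys[side]] / replicates))
    log = {"replicates": replicates, "resampled_degenerate": resampled}
    return tree, log


def _newick_node(node: TreeNode) -> str:
    if node.is_leaf:
        return f"{node.name}:{node.length:.6f}"
    inner = ",".join(_newick_node(ch) for ch in node.children)
    label = "" if node.support is None else str(node.support)
    return f"({inner}){label}:{node.length:.6f}"


def to_newick(tree: PhyloTree) -> str:
    """Newick string: branch lengths to 6 decimals, supports as node labels."""
    root = tree.root
    inner = ",".join(_newick_node(ch) for ch in root.children)
    label = "" if root.support is None else str(root.support)
    return f"({inner}){label};"


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n", encoding="utf-8")
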