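import numpy as np
import pytest

from degrinscan.phylo import (
    Alignment,
    DistanceMatrix,
    bootstrap_support,
    neighbor_joining,
    p_distance,
    read_alignment,
    to_newick,
    write_newick,
)
from degrinscan.simulate import (
    distance_matrix_from_tree,
    generate_alignment_fixture,
    random_binary_tree,
)


class TestReadAlignment:
    def test_fasta_alignment(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\nAC-DE\n>b\nacgde\n")
        aln = read_alignment(p, "fasta")
        assert aln.n_cols == 5 and aln.rows == ["AC-DE", "ACGDE"]

    def test_ragged_rows_error_names_id(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\nACDE\n>b\nACD\n")
        with pytest.raises(ValueError, match="'b'"):
            read_alignment(p, "fasta")

    def test_clustal_equals_fasta(self, tmp_path):
        rows = {"s1": "ACDEF-HIKL", "s2": "ACDEFGHIKL", "s3": "AC-EFGHIKL"}
        fa = tmp_path / "aln.fasta"
        fa.write_text("".join(f">{k}\n{v}\n" for k, v in rows.items()))
        cl = tmp_path / "aln.aln"
        body = "\n".join(f"{k:<10}{v}" for k, v in rows.items())
        cl.write_text("CLUSTAL W (1.83) multiple sequence alignment\n\n\n" + body + "\n")
        a1 = read_alignment(fa, "fasta")
        a2 = read_alignment(cl, "clustal")
        assert a1.ids == a2.ids and a1.rows == a2.rows


class TestPDistance:
    def test_identical_rows_zero(self):
        dm = p_distance(Alignment(["a", "b"], ["ACDE", "ACDE"]))
        assert dm.d[0, 1] == 0.0

    def test_half_mismatch(self):
        dm = p_distance(Alignment(["a", "b"], ["AAAA", "AATT"]))
        assert dm.d[0, 1] == pytest.approx(0.5)

    def test_pairwise_gap_deletion(self):
        dm = p_distance(Alignment(["a", "b"], ["A-AA", "AAAA"]))
        assert dm.d[0, 1] == 0.0

    def test_zero_comparable_columns_error(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance(Alignment(["a", "b"], ["A--", "-AA"]))

    def test_symmetry_zero_diagonal_range(self):
        rng = np.random.default_rng(1)
        rows = ["".join(rng.choice(list("ACDEFG-"), size=40)) for _ in range(5)]
        aln = Alignment([f"t{i}" for i in range(5)], rows)
        dm = p_distance(aln)
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0)
        assert ((dm.d >= 0) & (dm.d <= 1)).all()


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]))
        tree = neighbor_joining(dm)
        assert to_newick(tree) == "(A:0.050000,B:0.150000,C:0.250000);"

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 0.1], [0.1, 0]]))
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_additive_recovery_random_trees(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            true = random_binary_tree(int(rng.integers(5, 13)), rng)
            dm = distance_matrix_from_tree(true)
            rec = neighbor_joining(dm)
            assert rec.splits() == true.splits()
            p_true, p_rec = true.path_lengths(), rec.path_lengths()
            for pair in p_true:
                assert p_rec[pair] == pytest.approx(p_true[pair], abs=1e-9)

    def test_all_equal_distances_deterministic(self):
        n = 6
        d = np.full((n, n), 0.4)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix([f"t{i}" for i in range(n)], d)
        first = to_newick(neighbor_joining(dm))
        for _ in range(3):
            assert to_newick(neighbor_joining(dm)) == first

    def test_negative_branch_lengths_clamped(self):
        # non-additive matrix known to yield a negative NJ branch estimate
        d = np.array(
            [[0, 0.1, 0.4, 0.5],
             [0.1, 0, 0.45, 0.55],
             [0.4, 0.45, 0, 0.05],
             [0.5, 0.55, 0.05, 0]]
        )
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        lengths = [n.length for n in tree.root.walk() if n is not tree.root]
        raws = [n.raw_length for n in tree.root.walk() if n is not tree.root]
        assert all(l >= 0 for l in lengths)
        assert min(raws) <= min(lengths)  # raw values retained pre-clamp

    def test_agrees_with_skbio_on_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(23)
        for _ in range(5):
            true = random_binary_tree(8, rng)
            dm = distance_matrix_from_tree(true)
            mine = neighbor_joining(dm)
            sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dm.d, ids=dm.ids))
            sk_d = sk_tree.tip_tip_distances(endpoints=dm.ids)
            my_paths = mine.path_lengths()
            for (a, b), val in my_paths.items():
                assert sk_d[a, b] == pytest.approx(val, abs=1e-6)


class TestBootstrap:
    def test_perfect_split_gets_full_support(self):
        aln = generate_alignment_fixture(
            {"taxa": ["A", "B", "C", "D"], "splits": [(["A", "B"], 40)]},
            n_cols=40, seed=2,
        )
        tree, log = bootstrap_support(aln, replicates=100, seed=9)
        supports = [n.support for n in tree.bipartitions().values()]
        assert supports == [100]
        assert log["replicates"] == 100

    def test_seed_determinism(self):
        aln = generate_alignment_fixture(
            {"taxa": list("ABCDEF"),
             "splits": [(["A", "B"], 10), (["A", "B", "C"], 6), (["E", "F"], 8)]},
            n_cols=40, seed=4,
        )
        t1, _ = bootstrap_support(aln, replicates=50, seed=123)
        t2, _ = bootstrap_support(aln, replicates=50, seed=123)
        assert to_newick(t1) == to_newick(t2)

    def test_mixed_columns_intermediate_support(self):
        # two incompatible splits contributing half the columns each:
        # neither can be supported by every replicate
        aln = generate_alignment_fixture(
            {"taxa": ["A", "B", "C", "D"],
             "splits": [(["A", "B"], 10), (["A", "C"], 10)]},
            n_cols=20, seed=6,
        )
        tree, _ = bootstrap_support(aln, replicates=200, seed=11)
        supports = [n.support for n in tree.bipartitions().values()]
        assert supports and all(0 <= s <= 100 for s in supports)
        assert any(0 < s < 100 for s in supports)

    def test_supports_invariant_to_leaf_order(self):
        aln = generate_alignment_fixture(
            {"taxa": list("ABCDE"), "splits": [(["A", "B"], 20), (["D", "E"], 20)]},
            n_cols=40, seed=8,
        )
        perm = Alignment(list(reversed(aln.ids)), list(reversed(aln.rows)))
        t1, _ = bootstrap_support(aln, replicates=100, seed=5)
        t2, _ = bootstrap_support(perm, replicates=100, seed=5)

        def canonical(tree):
            # orientation-free split -> support
            allv = tree.leaf_names()
            return {
                frozenset((side, allv - side)): node.support
                for side, node in tree.bipartitions().items()
            }

        assert canonical(t1) == canonical(t2)


class TestNewick:
    def test_three_leaf_form(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]))
        assert to_newick(neighbor_joining(dm)) == "(A:0.050000,B:0.150000,C:0.250000);"

    def test_supports_appear_after_internal_paren(self):
        aln = generate_alignment_fixture(
            {"taxa": ["A", "B", "C", "D"], "splits": [(["A", "B"], 30)]},
            n_cols=30, seed=3,
        )
        tree, _ = bootstrap_support(aln, replicates=20, seed=1)
        nwk = to_newick(tree)
        assert ")100:" in nwk

    def test_round_trip_with_dendropy(self, tmp_path):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(31)
        for _ in range(5):
            tree = random_binary_tree(int(rng.integers(4, 10)), rng)
            path = tmp_path / "t.nwk"
            write_newick(tree, path)
            dt = dendropy.Tree.get(path=str(path), schema="newick")
            pdm = dt.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in dt.taxon_namespace}
            for (a, b), val in tree.path_lengths().items():
                assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(val, abs=1e-5)
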