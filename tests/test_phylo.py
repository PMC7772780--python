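import numpy as np
import pytest

from cageatlas import (
    Alignment,
    DistanceMatrix,
    bootstrap_support,
    from_newick,
    nj_tree,
    p_distance,
    to_newick,
    tree_splits,
)
from oracles import random_additive_tree


class TestPDistance:
    def test_identical_rows_zero(self):
        dm = p_distance(Alignment(["a", "b"], ["ACGT", "ACGT"]))
        assert dm.d[0, 1] == 0

    def test_one_mismatch_in_four(self):
        dm = p_distance(Alignment(["a", "b"], ["AAAA", "AAAT"]))
        assert dm.d[0, 1] == 0.25

    def test_gap_columns_excluded(self):
        dm = p_distance(Alignment(["a", "b"], ["A-CG", "AACG"]))
        assert dm.d[0, 1] == 0.0

    def test_all_gap_pair_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance(Alignment(["a", "b"], ["A---", "-CCC"]))

    def test_symmetric_bounded(self, rng):
        rows = ["".join(rng.choice(list("ACGT-"), size=30)) for _ in range(5)]
        try:
            dm = p_distance(Alignment([f"t{i}" for i in range(5)], rows))
        except ValueError:
            return
        assert np.allclose(dm.d, dm.d.T)
        assert (dm.d <= 1).all() and (dm.d >= 0).all()
        assert np.allclose(np.diag(dm.d), 0)


def three_taxon_dm():
    d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    return DistanceMatrix(["A", "B", "C"], d)


class TestNJ:
    def test_three_taxon_closed_form(self):
        tree = nj_tree(three_taxon_dm())
        lengths = {t.name: t.branch_length for t in tree.get_terminals()}
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(2.0),
                           "C": pytest.approx(3.0)}

    def test_needs_three_taxa(self):
        with pytest.raises(ValueError, match=">= 3"):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_asymmetric_rejected(self):
        d = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"], d)

    def test_recovers_additive_four_taxon_tree(self):
        # tree ((A:1,B:2):1,(C:3,D:4)); path distances are additive
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(DistanceMatrix(["A", "B", "C", "D"], d))
        assert tree_splits(tree) == {frozenset({"C", "D"})}
        # total tree length: 1+2+1+3+4 = 11
        total = sum(c.branch_length for c in tree.find_clades() if c.branch_length)
        assert total == pytest.approx(11.0, abs=1e-9)

    def test_topology_recovery_on_random_additive_matrices(self):
        rng = np.random.default_rng(60)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            splits, d, taxa = random_additive_tree(n, rng)
            tree = nj_tree(DistanceMatrix(taxa, d))
            assert tree_splits(tree) == splits

    def test_matches_independent_nj_implementation(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(8)
        splits, d, taxa = random_additive_tree(6, rng)
        # perturb slightly so the check is not purely the additive case
        noise = rng.normal(0, 0.01, size=d.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        d2 = np.abs(d + noise)
        d2 = (d2 + d2.T) / 2
        tree = nj_tree(DistanceMatrix(taxa, d2))
        csv = "," + ",".join(taxa) + "\n"
        for i, t in enumerate(taxa):
            csv += t + "," + ",".join(f"{x:.10f}" for x in d2[i]) + "\n"
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(io.StringIO(csv))
        dtree = pdm.nj_tree()
        dsplits = set()
        leaves = {l.taxon.label for l in dtree.leaf_node_iter()}
        anchor = min(leaves)
        for node in dtree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = {l.taxon.label for l in node.leaf_iter()}
            if 2 <= len(side) <= len(leaves) - 2:
                dsplits.add(frozenset(leaves - side if anchor in side else side))
        assert tree_splits(tree) == dsplits


def congruent_alignment():
    """Every column supports the same AB|CD split."""
    cols = [("A", "A", "C", "C"), ("T", "T", "G", "G")]
    rows = ["".join(cols[i % 2][k] for i in range(40)) for k in range(4)]
    return Alignment(["A", "B", "C", "D"], rows)


class TestBootstrap:
    def test_perfect_congruence_gives_full_support(self):
        tree = bootstrap_support(congruent_alignment(), B=50, seed=3)
        supports = [c.confidence for c in tree.get_nonterminals() if c.confidence is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(10)
        rows = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(5)]
        aln = Alignment([f"t{i}" for i in range(5)], rows)
        t1 = bootstrap_support(aln, B=30, seed=11)
        t2 = bootstrap_support(aln, B=30, seed=11)
        assert to_newick(t1) == to_newick(t2)

    def test_supports_in_range_and_order_invariant(self):
        rng = np.random.default_rng(12)
        rows = ["".join(rng.choice(list("ACGT"), size=80)) for _ in range(5)]
        taxa = [f"t{i}" for i in range(5)]
        aln = Alignment(taxa, rows)
        t1 = bootstrap_support(aln, B=40, seed=5)

        def support_by_split(tree):
            out = {}
            leaves = {t.name for t in tree.get_terminals()}
            anchor = min(leaves)
            for c in tree.get_nonterminals():
                if c.confidence is None:
                    continue
                side = {t.name for t in c.get_terminals()}
                key = frozenset(leaves - side if anchor in side else side)
                out[key] = c.confidence
            return out

        s1 = support_by_split(t1)
        assert all(0 <= v <= 100 for v in s1.values())
        order = [3, 1, 4, 0, 2]
        aln2 = Alignment([taxa[i] for i in order], [rows[i] for i in order])
        s2 = support_by_split(bootstrap_support(aln2, B=40, seed=5))
        assert set(s1) == set(s2)

    def test_invalid_b_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(congruent_alignment(), B=0)


class TestNewick:
    def test_three_taxon_star(self):
        text = to_newick(nj_tree(three_taxon_dm()))
        stripped = text.replace(" ", "")
        for token in ("A:1", "B:2", "C:3"):
            assert token in stripped

    def test_round_trip_preserves_splits(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 8))
            splits, d, taxa = random_additive_tree(n, rng)
            tree = nj_tree(DistanceMatrix(taxa, d))
            again = from_newick(to_newick(tree))
            assert tree_splits(again) == tree_splits(tree)

    def test_supports_survive_round_trip(self):
        tree = bootstrap_support(congruent_alignment(), B=20, seed=1)
        again = from_newick(to_newick(tree))
        sup = [c.confidence for c in again.get_nonterminals() if c.confidence is not None]
        assert sup and all(s == 100 for s in sup)
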