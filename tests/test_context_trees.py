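"""Variable-group clustering, tree cuts and the Fowlkes–Mallows index."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from conftest import fm_pair_counting, random_partition
from olscontext.context_trees import (
    ContextTree,
    Partition,
    cut_k,
    cut_tree,
    data_grouping_correlation,
    fowlkes_mallows,
    restrict_tree,
    single_group_partition,
    vg_ahc,
)


def random_tie_free_matrix(rng, n):
    """Random symmetric matrix with all pairwise values distinct."""
    vals = rng.permutation(np.arange(1, n * (n - 1) // 2 + 1)) + rng.random(
        n * (n - 1) // 2
    ) * 0.5
    return DistanceMatrix(squareform(vals), ids=[f"L{i}" for i in range(n)])


def cophenetic_of(tree: ContextTree):
    """Height of the lowest common ancestor for every leaf pair."""
    ids = sorted(tree.leaf_ids())
    index = {l: i for i, l in enumerate(ids)}
    n = len(ids)
    coph = np.zeros((n, n))

    def walk(node):
        if node.is_leaf:
            return [node.leaf_id]
        sub = [walk(c) for c in node.children]
        for a in range(len(sub)):
            for b in range(a + 1, len(sub)):
                for la in sub[a]:
                    for lb in sub[b]:
                        i, j = index[la], index[lb]
                        coph[i, j] = coph[j, i] = node.height
        return [l for s in sub for l in s]

    walk(tree.root)
    return ids, coph


SCIPY_METHOD = {"unweighted_average": "average", "complete": "complete"}


class TestVgAhc:
    @pytest.mark.parametrize("linkage_name", ["unweighted_average", "complete"])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sequential_oracle_without_ties(self, linkage_name, seed):
        """Tie-free matrices: identical dendrogram to scipy's sequential AHC
        (compared through cophenetic heights, which determine the tree)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        dm = random_tie_free_matrix(rng, n)
        tree = vg_ahc(dm, linkage=linkage_name)
        ids, coph = cophenetic_of(tree)
        Z = linkage(squareform(dm.data), method=SCIPY_METHOD[linkage_name])
        expected = squareform(cophenet(Z))
        order = [list(dm.ids).index(l) for l in ids]
        assert np.allclose(coph, expected[np.ix_(order, order)], atol=1e-9)

    def test_all_equal_distances_single_multifurcation(self):
        dm = DistanceMatrix(
            np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float),
            ids=["a", "b", "c"],
        )
        tree = vg_ahc(dm)
        assert len(tree.root.children) == 3
        assert tree.root.height == pytest.approx(1.0)

    def test_single_leaf(self):
        tree = vg_ahc(DistanceMatrix([[0.0]], ids=["only"]))
        assert tree.root.is_leaf and tree.leaf_ids() == ["only"]

    def test_empty_rejected(self):
        with pytest.raises(Exception):
            vg_ahc(DistanceMatrix(np.zeros((0, 0)), ids=[]))

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_heights_monotone(self, seed):
        rng = np.random.default_rng(50 + seed)
        dm = random_tie_free_matrix(rng, 7)
        tree = vg_ahc(dm)

        def check(node):
            for c in node.children:
                assert c.height <= node.height + 1e-12
                check(c)

        check(tree.root)

    def test_newick_export_heights_as_branch_lengths(self):
        dm = DistanceMatrix(
            np.array([[0, 0.2, 1.0], [0.2, 0, 1.0], [1.0, 1.0, 0]]),
            ids=["a", "b", "c"],
        )
        nwk = vg_ahc(dm).to_newick()
        # leaf branch length = parent merge height − leaf height (0)
        assert "a:0.2" in nwk and "c:1" in nwk


class TestCutTree:
    def _tree(self):
        dm = DistanceMatrix(
            np.array([[0, 0.04, 0.2], [0.04, 0, 0.2], [0.2, 0.2, 0]]),
            ids=["A", "B", "C"],
        )
        return vg_ahc(dm)

    def test_cut_above_root_single_block(self):
        t = self._tree()
        assert len(cut_tree(t, 1.0)) == 1

    def test_cut_below_all_merges_singletons(self):
        t = self._tree()
        assert len(cut_tree(t, 0.01)) == 3

    def test_cut_between_merges(self):
        t = self._tree()
        p = cut_tree(t, 0.05)
        assert set(p.blocks) == {frozenset({"A", "B"}), frozenset({"C"})}

    def test_cut_k_removes_highest_merges(self):
        t = self._tree()
        assert len(cut_k(t, 1)) == 1
        p2 = cut_k(t, 2)
        assert set(p2.blocks) == {frozenset({"A", "B"}), frozenset({"C"})}
        assert len(cut_k(t, 3)) == 3


class TestFowlkesMallows:
    def test_identical_partitions(self):
        p = Partition(blocks=[{"a", "b"}, {"c"}])
        assert fowlkes_mallows(p, p) == pytest.approx(1.0)

    def test_crossed_pairs_zero(self):
        p1 = Partition(blocks=[{"a", "b"}, {"c", "d"}])
        p2 = Partition(blocks=[{"a", "c"}, {"b", "d"}])
        assert fowlkes_mallows(p1, p2) == 0.0

    def test_all_singletons_convention(self):
        p1 = Partition(blocks=[{"a", "b"}, {"c"}])
        p2 = Partition(blocks=[{"a"}, {"b"}, {"c"}])
        assert fowlkes_mallows(p1, p2) == 0.0

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fowlkes_mallows(
                Partition(blocks=[{"a"}]), Partition(blocks=[{"b"}])
            )

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"x{i}" for i in range(int(rng.integers(4, 12)))]
        b1 = random_partition(rng, labels, int(rng.integers(1, 5)))
        b2 = random_partition(rng, labels, int(rng.integers(1, 5)))
        got = fowlkes_mallows(Partition(blocks=b1), Partition(blocks=b2))
        assert got == pytest.approx(fm_pair_counting(b1, b2), abs=1e-12)
        # symmetry
        assert got == pytest.approx(
            fowlkes_mallows(Partition(blocks=b2), Partition(blocks=b1))
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_cross_check_against_sklearn(self, seed):
        from sklearn.metrics import fowlkes_mallows_score

        rng = np.random.default_rng(100 + seed)
        labels = [f"x{i}" for i in range(10)]
        b1 = random_partition(rng, labels, 3)
        b2 = random_partition(rng, labels, 3)
        l1 = {x: i for i, b in enumerate(b1) for x in b}
        l2 = {x: i for i, b in enumerate(b2) for x in b}
        ref = fowlkes_mallows_score(
            [l1[x] for x in labels], [l2[x] for x in labels]
        )
        got = fowlkes_mallows(Partition(blocks=b1), Partition(blocks=b2))
        assert got == pytest.approx(ref, abs=1e-9)


class TestFowlkesMallowsHypothesis:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    labels = [f"e{i}" for i in range(8)]
    assignment = st.lists(
        st.integers(min_value=0, max_value=3), min_size=8, max_size=8
    )

    @staticmethod
    def _blocks(assign):
        blocks = {}
        for lab, a in zip(TestFowlkesMallowsHypothesis.labels, assign):
            blocks.setdefault(a, set()).add(lab)
        return [frozenset(b) for b in blocks.values()]

    @given(a1=assignment, a2=assignment)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounds_symmetry_and_equality_iff_one(self, a1, a2):
        p1 = Partition(blocks=self._blocks(a1))
        p2 = Partition(blocks=self._blocks(a2))
        b = fowlkes_mallows(p1, p2)
        assert 0.0 <= b <= 1.0 + 1e-12
        assert b == pytest.approx(fowlkes_mallows(p2, p1))
        if p1 == p2 and len(p1) < len(p1.universe):
            assert b == pytest.approx(1.0)
        if b == pytest.approx(1.0):
            assert p1 == p2


class TestDataGroupingCorrelation:
    def _tree(self, d_ab=0.04, d_c=0.2):
        dm = DistanceMatrix(
            np.array([[0, d_ab, d_c], [d_ab, 0, d_c], [d_c, d_c, 0]]),
            ids=["A", "B", "C"],
        )
        return vg_ahc(dm, species_of={"A": "A", "B": "B", "C": "C"})

    def test_shallow_tree_agrees_with_single_group(self):
        tree = self._tree(d_ab=0.01, d_c=0.04)
        score, agrees = data_grouping_correlation(
            tree, single_group_partition(["A", "B", "C"])
        )
        assert agrees and score == pytest.approx(1.0)

    def test_deep_merge_disagrees(self):
        tree = self._tree(d_ab=0.04, d_c=0.9)
        _, agrees = data_grouping_correlation(
            tree, single_group_partition(["A", "B", "C"])
        )
        assert not agrees

    def test_matching_partition_scores_one(self):
        tree = self._tree()
        g = Partition(blocks=[{"A", "B"}, {"C"}])
        score, agrees = data_grouping_correlation(tree, g, 0.05)
        assert agrees and score == pytest.approx(1.0)

    def test_missing_species_rejected(self):
        tree = self._tree()
        with pytest.raises(ValueError):
            data_grouping_correlation(tree, Partition(blocks=[{"A", "B"}]))

    def test_k_mode(self):
        tree = self._tree()
        g = Partition(blocks=[{"A", "B"}, {"C"}])
        score, agrees = data_grouping_correlation(tree, g, 2, mode="k")
        assert agrees and score == pytest.approx(1.0)


class TestRestrictTree:
    def test_restriction_collapses_unary_nodes(self):
        dm = DistanceMatrix(
            np.array(
                [
                    [0, 0.1, 0.5, 0.9],
                    [0.1, 0, 0.5, 0.9],
                    [0.5, 0.5, 0, 0.9],
                    [0.9, 0.9, 0.9, 0],
                ]
            ),
            ids=["A", "B", "C", "D"],
        )
        t = vg_ahc(dm, species_of={x: x for x in "ABCD"})
        r = restrict_tree(t, {"A", "C", "D"})
        assert sorted(r.leaf_ids()) == ["A", "C", "D"]
        # A's old parent (the AB merge) must be gone
        assert all(len(n.children) >= 2 for n in r.root.internal_nodes())
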