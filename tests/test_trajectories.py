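"""Trajectory metrics, content collections and modification classification."""

from collections import Counter

import pytest
from skbio import DistanceMatrix

from conftest import make_grouping, make_trajectory
from olscontext.trajectories import (
    Trajectory,
    TrajectoryGrouping,
    build_trajectory,
    classify_modifications,
    clustericity,
    content_collections,
    phylogeny_disagreement,
    select_seed_families,
    topology_divergence_ratio,
    variety,
)


class TestSeedSelection:
    def _ols(self, fams, sp, multigene=True):
        return make_grouping(fams, species_id=sp)

    def test_species_and_instance_thresholds(self):
        # F1 in 3 species (multigene), F2 in 2, F3 in 3 but only singletons
        ols = {
            f"sp{i}": [
                make_grouping(["F1", "X"], species_id=f"sp{i}"),
                make_grouping(["F3"], species_id=f"sp{i}", start=90_000),
            ]
            for i in range(3)
        }
        ols["sp0"].append(make_grouping(["F2", "Y"], species_id="sp0", start=50_000))
        ols["sp1"].append(make_grouping(["F2", "Y"], species_id="sp1", start=50_000))
        homology = {}
        got = select_seed_families(homology, ols, min_species=3, max_instances=100)
        assert got == ["F1", "X"]  # F2: 2 species; F3: no multigene OLS

    def test_instance_cap_excludes_family(self):
        ols = {
            f"sp{i}": [make_grouping(["F1", "F1", "X"], species_id=f"sp{i}")]
            for i in range(4)
        }
        assert "F1" in select_seed_families({}, ols, min_species=4, max_instances=8)
        assert "F1" not in select_seed_families({}, ols, min_species=4, max_instances=7)


class TestBuildTrajectory:
    def test_single_ols_keeps_order(self):
        ols = {"sp1": [make_grouping(["S", "A"], species_id="sp1")]}
        t = build_trajectory("S", ols)
        assert t.groupings["sp1"].content == Counter({"S": 1, "A": 1})
        assert t.groupings["sp1"].ordered is not None

    def test_same_species_copies_merge_as_multiset(self):
        ols = {
            "sp1": [
                make_grouping(["S", "A"], species_id="sp1"),
                make_grouping(["S", "B"], species_id="sp1", start=50_000),
            ]
        }
        t = build_trajectory("S", ols)
        g = t.groupings["sp1"]
        assert g.content == Counter({"S": 2, "A": 1, "B": 1})
        assert g.ordered is None  # merged grouping has no linear order

    def test_singleton_flag(self):
        ols = {"sp1": [make_grouping(["S"], species_id="sp1")]}
        t = build_trajectory("S", ols)
        assert t.groupings["sp1"].singleton

    def test_absent_seed_is_error(self):
        with pytest.raises(ValueError):
            build_trajectory("Z", {"sp1": [make_grouping(["S"], species_id="sp1")]})


class TestClustericity:
    def test_five_of_six_multigene(self):
        """Six organisms, seed multigene in five, singleton in one → 0.83."""
        per_species = {f"org{i}": ["S", f"A{i}"] for i in range(5)}
        per_species["org5"] = ["S"]
        t = make_trajectory("S", per_species)
        assert round(clustericity(t), 2) == 0.83

    def test_extremes(self):
        assert clustericity(make_trajectory("S", {"a": ["S", "A"], "b": ["S", "B"]})) == 1.0
        assert clustericity(make_trajectory("S", {"a": ["S"], "b": ["S"]})) == 0.0


class TestVariety:
    def test_one_type_three_copies(self):
        t = make_trajectory("S", {f"sp{i}": ["S", "A"] for i in range(3)})
        assert variety(t) == pytest.approx(1 / 3)

    def test_all_distinct(self):
        t = make_trajectory("S", {"a": ["S", "A"], "b": ["S", "B"], "c": ["S", "C"]})
        assert variety(t) == 1.0

    def test_all_singletons_zero(self):
        t = make_trajectory("S", {"a": ["S"], "b": ["S"]})
        assert variety(t) == 0.0

    def test_bounded_unit_interval(self):
        t = make_trajectory(
            "S", {"a": ["S", "A", "A", "B"], "b": ["S", "A"], "c": ["S"]}
        )
        assert 0.0 <= variety(t) <= 1.0 and 0.0 <= clustericity(t) <= 1.0


class TestContentCollections:
    def test_multiset_partition(self):
        t = make_trajectory("S", {"a": ["S", "A"], "b": ["S", "A"], "c": ["S"]})
        assert len(content_collections(t)) == 2

    def test_all_identical(self):
        t = make_trajectory("S", {"a": ["S", "A"], "b": ["S", "A"]})
        assert len(content_collections(t)) == 1

    def test_paralog_copies_distinguish(self):
        t = make_trajectory("S", {"a": ["S", "A", "A"], "b": ["S", "A"]})
        assert len(content_collections(t)) == 2

    def test_at_most_one_collection_per_species(self):
        t = make_trajectory(
            "S", {"a": ["S", "A"], "b": ["S", "B"], "c": ["S", "A"], "d": ["S"]}
        )
        cols = content_collections(t)
        assert len(cols) <= len(t.groupings)
        seen = [sp for c in cols for sp in c.species]
        assert sorted(seen) == sorted(t.groupings)


class TestTopologyDivergence:
    def _pd(self, species, d):
        import numpy as np

        n = len(species)
        m = np.zeros((n, n))
        for (a, b), v in d.items():
            i, j = species.index(a), species.index(b)
            m[i, j] = m[j, i] = v
        return DistanceMatrix(m, ids=species)

    def test_identical_content(self):
        t = make_trajectory("S", {"a": ["S", "A"], "b": ["S", "A"]})
        pd = self._pd(["a", "b"], {("a", "b"): 0.5})
        assert topology_divergence_ratio(t, pd) == pytest.approx(1 / 0.5)

    def test_two_distinct_contents(self):
        t = make_trajectory("S", {"a": ["S", "A"], "b": ["S", "B"]})
        pd = self._pd(["a", "b"], {("a", "b"): 0.5})
        assert topology_divergence_ratio(t, pd) == pytest.approx(4.0)

    def test_single_species_undefined(self):
        t = make_trajectory("S", {"a": ["S", "A"]})
        pd = self._pd(["a"], {})
        assert topology_divergence_ratio(t, pd) is None


class TestClassifyModifications:
    def test_prepend(self):
        t = make_trajectory("A", {"a": ["A", "B"], "b": ["X", "A", "B"]})
        events, label = classify_modifications(t)
        assert [e.kind for e in events] == ["prepend"]
        assert label == "single_type"

    def test_append(self):
        t = make_trajectory("A", {"a": ["A", "B"], "b": ["A", "B", "X"]})
        events, _ = classify_modifications(t)
        assert [e.kind for e in events] == ["append"]

    def test_append_on_minus_strand(self):
        t = make_trajectory(
            "A", {"a": (["A", "B"], "-"), "b": (["A", "B", "X"], "-")}
        )
        events, _ = classify_modifications(t)
        assert [e.kind for e in events] == ["append"]

    def test_insertion(self):
        t = make_trajectory("A", {"a": ["A", "B", "C"], "b": ["A", "X", "B", "C"]})
        events, _ = classify_modifications(t)
        assert [e.kind for e in events] == ["insertion"]

    def test_pairs_need_two_genes_each(self):
        t = make_trajectory("A", {"a": ["A"], "b": ["A", "X"]})
        events, label = classify_modifications(t)
        assert events == [] and label == "none"

    def test_multiple_types_label(self):
        t = make_trajectory(
            "A",
            {
                "a": ["A", "B"],
                "b": ["X", "A", "B"],
                "c": ["A", "B", "Y"],
            },
        )
        _, label = classify_modifications(t)
        assert label == "multiple_types"

    def test_ambiguous_extra_family_flagged(self):
        # extra copy of B could sit at interior or tail of the larger OLS
        t = make_trajectory("A", {"a": ["A", "B"], "b": ["A", "B", "B"]})
        events, _ = classify_modifications(t)
        assert len(events) == 1 and events[0].ambiguous

    def test_unordered_representative_skipped(self):
        small = make_grouping(["A", "B"], species_id="a")
        t = Trajectory(
            seed_family="A",
            groupings={
                "a": TrajectoryGrouping(
                    "a", Counter({"A": 1, "B": 1}), 2, ordered=small
                ),
                "b": TrajectoryGrouping(
                    "b", Counter({"A": 1, "B": 1, "X": 1}), 3, ordered=None
                ),
            },
        )
        events, label = classify_modifications(t)
        assert events == [] and label == "none"


class TestPhylogenyDisagreement:
    def _pd(self, d):
        import numpy as np

        species = sorted({s for pair in d for s in pair})
        n = len(species)
        m = np.zeros((n, n))
        for (a, b), v in d.items():
            i, j = species.index(a), species.index(b)
            m[i, j] = m[j, i] = v
        return DistanceMatrix(m, ids=species)

    def test_single_collection_never_disagrees(self):
        t = make_trajectory("S", {"a": ["S", "A"], "b": ["S", "A"]})
        pd = self._pd({("a", "b"): 5.0})
        assert not phylogeny_disagreement(t, pd)

    def test_spread_cluster_disagrees(self):
        t = make_trajectory("S", {"a": ["S", "A"], "b": ["S", "A"], "o": ["S", "B"]})
        pd = self._pd({("a", "b"): 0.5, ("a", "o"): 0.2, ("b", "o"): 0.2})
        assert phylogeny_disagreement(t, pd, margin=0.10)

    def test_margin_suppresses_borderline(self):
        t = make_trajectory("S", {"a": ["S", "A"], "b": ["S", "A"], "o": ["S", "B"]})
        pd = self._pd({("a", "b"): 0.5, ("a", "o"): 0.45, ("b", "o"): 0.45})
        assert not phylogeny_disagreement(t, pd, margin=0.10)

    def test_excluding_singletons_can_remove_disagreement(self):
        # the far-flung members are singletons; excluding them leaves one
        # tight collection
        t = make_trajectory(
            "S", {"a": ["S", "A"], "b": ["S"], "c": ["S"], "o": ["S", "B"]}
        )
        pd = self._pd(
            {
                ("a", "b"): 0.1,
                ("a", "c"): 0.1,
                ("b", "c"): 2.0,
                ("a", "o"): 0.1,
                ("b", "o"): 0.1,
                ("c", "o"): 0.1,
            }
        )
        assert phylogeny_disagreement(t, pd, include_singletons=True)
        assert not phylogeny_disagreement(t, pd, include_singletons=False)

    def test_min_inter_variant_is_stricter(self):
        t = make_trajectory("S", {"a": ["S", "A"], "b": ["S", "A"], "o": ["S", "B"]})
        pd = self._pd({("a", "b"): 0.5, ("a", "o"): 0.2, ("b", "o"): 0.9})
        assert not phylogeny_disagreement(t, pd, compare="max_inter")
        assert phylogeny_disagreement(t, pd, compare="min_inter")
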