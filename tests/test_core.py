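import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pks.core import (
    PairDifference,
    PKSProfile,
    StandardPathwayList,
    build_standard_list,
    find_clusters,
    make_pks_profile,
    pks_difference,
    round_pct,
    summarize_related_pairs,
)
from pks.pathways import PathwayCallSet

from conftest import make_pks


def callset(sample_id, pathways):
    return PathwayCallSet(
        sample_id=sample_id, pathways=frozenset(pathways),
        covered_ecs=frozenset(), orphan_ecs=frozenset(),
    )


def plist(n, species="sp", depth=1000):
    return StandardPathwayList(
        species_id=species, depth=depth,
        map_ids=tuple(f"map{i + 1:05d}" for i in range(n)),
    )


class TestRoundPct:
    @pytest.mark.parametrize("value,expected", [
        (37.142857, 37.1), (17.647, 17.6), (81.8181, 81.8), (82.3529, 82.4),
        (0.05, 0.1), (0.04999, 0.0), (99.95, 100.0),
    ])
    def test_half_away_from_zero(self, value, expected):
        assert round_pct(value) == expected


class TestStandardPathwayList:
    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            StandardPathwayList("sp", 1, ("map2", "map1"))

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            StandardPathwayList("sp", 1, ("map1", "map1"))


class TestBuildStandardList:
    def test_union_over_related(self):
        callsets = {
            "a1": callset("a1", {"P1", "P2"}), "a2": callset("a2", {"P2"}),
            "b1": callset("b1", {"P3"}), "b2": callset("b2", {"P2"}),
        }
        rel = {("a1", "a2"): "related", ("b1", "b2"): "related"}
        result = build_standard_list(callsets, rel, "sp", 1000)
        assert result.map_ids == ("P1", "P2", "P3")

    def test_unrelated_pair_excluded(self):
        callsets = {
            "a1": callset("a1", {"P1"}), "a2": callset("a2", {"P1"}),
            "b1": callset("b1", {"P9"}), "b2": callset("b2", {"P9"}),
        }
        rel = {("a1", "a2"): "related", ("b1", "b2"): "unrelated"}
        assert build_standard_list(callsets, rel, "sp", 1).map_ids == ("P1",)

    def test_no_related_pairs_errors(self):
        callsets = {"a1": callset("a1", {"P1"}), "a2": callset("a2", {"P1"})}
        with pytest.raises(ValueError, match="no related pairs"):
            build_standard_list(callsets, {("a1", "a2"): "unrelated"}, "sp", 1)

    def test_unlabelled_sample_errors(self):
        callsets = {"a1": callset("a1", {"P1"}), "zz": callset("zz", {"P2"})}
        with pytest.raises(ValueError, match="zz"):
            build_standard_list(callsets, {("a1", "a1b"): "related"}, "sp", 1)


class TestMakePksProfile:
    def test_projection(self):
        pl = plist(2)
        profile = make_pks_profile(callset("s", {"map00001"}), pl)
        assert profile.vector == (1, 0)

    def test_empty_callset_all_zero(self):
        assert make_pks_profile(callset("s", set()), plist(3)).vector == (0, 0, 0)

    def test_superset_all_one(self):
        pl = plist(2)
        profile = make_pks_profile(
            callset("s", {"map00001", "map00002", "map99999"}), pl
        )
        assert profile.vector == (1, 1)


class TestPksDifference:
    def test_identical_zero(self):
        pl = plist(3)
        a = make_pks([1, 0, 1], pl)
        assert pks_difference(a, a).n_diff == 0

    def test_gain_and_loss(self):
        pl = plist(2)
        d = pks_difference(make_pks([1, 0], pl), make_pks([0, 1], pl))
        assert d.n_diff == 2
        assert d.delta == (-1, 1)

    def test_mismatched_lists_error(self):
        a = make_pks([1, 0, 0], plist(3))
        b = make_pks([1, 0, 0], plist(3, species="other"))
        with pytest.raises(ValueError, match="different standard"):
            pks_difference(a, b)

    def test_random_elementwise_oracle(self):
        rng = np.random.default_rng(9)
        pl = plist(23)
        for _ in range(200):
            va, vb = rng.integers(0, 2, size=23), rng.integers(0, 2, size=23)
            d = pks_difference(make_pks(va, pl), make_pks(vb, pl))
            assert d.n_diff == int(sum(1 for x, y in zip(va, vb) if x != y))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(10)
        pl = plist(8)
        va, vb = rng.integers(0, 2, size=8), rng.integers(0, 2, size=8)
        perm = rng.permutation(8)
        # permuting the pathway axis consistently leaves n_diff unchanged
        pl2 = plist(8, species="sp")  # same ids; reorder vectors only
        d1 = pks_difference(make_pks(va, pl), make_pks(vb, pl))
        d2 = pks_difference(make_pks(va[perm], pl2), make_pks(vb[perm], pl2))
        assert d1.n_diff == d2.n_diff


@given(st.data())
@settings(max_examples=150, deadline=None)
def test_hamming_metric_axioms(data):
    pl = plist(10)
    vec = st.lists(st.integers(0, 1), min_size=10, max_size=10)
    a = make_pks(data.draw(vec), pl)
    b = make_pks(data.draw(vec), pl)
    c = make_pks(data.draw(vec), pl)
    dab = pks_difference(a, b).n_diff
    dba = pks_difference(b, a).n_diff
    dac = pks_difference(a, c).n_diff
    dcb = pks_difference(c, b).n_diff
    assert dab == dba
    assert (dab == 0) == (a.vector == b.vector)
    assert dab <= dac + dcb


class TestSummarizeRelatedPairs:
    def _diffs(self, n_diffs, length=23, distinct=False):
        out = []
        for i, n in enumerate(n_diffs):
            delta = [0] * length
            for j in range(n):
                delta[j] = 1
            out.append(PairDifference(f"p{i}", n, tuple(delta)))
        return out

    def test_trivial_counts(self):
        diffs = self._diffs([0, 0, 3, 5])
        s = summarize_related_pairs(diffs)
        assert (s.n_zero, s.pct_zero) == (2, 50.0)
        assert (s.n_nonzero, s.pct_nonzero) == (2, 50.0)

    def test_paper_consistent_roundings(self):
        s = summarize_related_pairs(self._diffs([0] * 13 + [2] * 22, distinct=False))
        assert s.pct_zero == 37.1
        s = summarize_related_pairs(self._diffs([0] * 6 + [1] * 27, distinct=False))
        assert s.pct_nonzero == 81.8

    def test_zero_pairs_never_form_shared_group(self):
        diffs = self._diffs([0, 0, 0], distinct=False)
        assert summarize_related_pairs(diffs).shared_pattern_groups == ()

    def test_identical_nonzero_patterns_grouped(self):
        pl_len = 5
        delta = (1, 0, 0, -1, 0)
        diffs = [
            PairDifference("x", 2, delta),
            PairDifference("y", 2, delta),
            PairDifference("z", 1, (1, 0, 0, 0, 0)),
        ]
        s = summarize_related_pairs(diffs)
        assert s.shared_pattern_groups == (("x", "y"),)

    def test_pct_conservation(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(1, 60))
            diffs = self._diffs(list(rng.integers(0, 4, size=n)), distinct=False)
            s = summarize_related_pairs(diffs)
            assert abs(s.pct_zero + s.pct_nonzero - 100.0) <= 0.1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_related_pairs([])


class TestFindClusters:
    def _series(self, patterns, days):
        pl = plist(len(patterns[0]))
        return [
            make_pks(p, pl, sample_id=f"s_d{d}", day=d)
            for p, d in zip(patterns, days)
        ]

    def test_all_distinct_unique_resolved(self):
        series = self._series([[0, 0], [0, 1], [1, 0]], [1, 2, 3])
        report = find_clusters(series)
        assert report.classification == "unique"
        assert report.clusters == ()
        assert report.resolved is True

    def test_extinction_reappearance_narrative(self):
        # A,B,C,D,A,A,A at days 2,5,6,7,14,21,28: one cluster {2,14,21,28},
        # 1 reappearance event, unresolved
        a, b, c, d = [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0]
        series = self._series([a, b, c, d, a, a, a], [2, 5, 6, 7, 14, 21, 28])
        report = find_clusters(series)
        assert len(report.clusters) == 1
        assert report.clusters[0].member_days == (2, 14, 21, 28)
        assert report.cluster_membership_count == 4
        assert report.reappearance_events == (1,)
        assert report.classification == "shared"
        assert report.resolved is False

    def test_leading_cluster_resolved(self):
        a, b = [1, 0], [0, 1]
        report = find_clusters(self._series([a, a, b], [0, 1, 2]))
        assert report.clusters[0].member_days == (0, 1)
        assert report.clusters[0].reappearances == 0
        assert report.resolved is True

    def test_two_interleaved_clusters(self):
        a, b, u = [1, 0, 0], [0, 1, 0], [0, 0, 1]
        report = find_clusters(self._series([a, b, a, b, u], [0, 1, 2, 3, 4]))
        assert len(report.clusters) == 2
        assert report.cluster_membership_count == 4
        assert report.reappearance_events == (1, 1)
        assert report.resolved is True

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="two time points"):
            find_clusters(self._series([[1, 0]], [0]))

    def test_nonincreasing_days_error(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            find_clusters(self._series([[1, 0], [0, 1]], [3, 3]))

    def test_clusters_disjoint_membership_bounded(self):
        rng = np.random.default_rng(33)
        pl = plist(3)
        for _ in range(100):
            n = int(rng.integers(2, 12))
            series = [
                make_pks(rng.integers(0, 2, size=3), pl, day=i) for i in range(n)
            ]
            report = find_clusters(series)
            all_days = [d for c in report.clusters for d in c.member_days]
            assert len(all_days) == len(set(all_days))
            assert report.cluster_membership_count == len(all_days) <= n
            assert (report.classification == "shared") == bool(report.clusters)

    def test_report_json_round_trip(self):
        from pks.core import ClusterReport

        a = [1, 0]
        report = find_clusters(self._series([a, a], [0, 5]))
        assert ClusterReport.from_dict(report.to_dict()) == report
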