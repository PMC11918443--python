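"""Hierarchical clustering, enrichment criterion, and elbow k-means."""

import numpy as np
import pytest
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from adstage.clustering import (
    average_linkage,
    correlation_distance,
    cut_k,
    enriched_cluster_test,
    first_branch_split,
    kmeans_with_elbow,
)


class TestCorrelationDistance:
    def test_identical_and_anti_proportional_columns(self):
        x = np.array([[1.0, 1.0, -1.0], [2.0, 2.0, -2.0], [3.0, 3.0, -3.0]])
        d = correlation_distance(x)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_matches_pairwise_pearson_loop(self, rng):
        x = rng.normal(size=(20, 8))
        d = correlation_distance(x)
        for i in range(8):
            for j in range(8):
                r = np.corrcoef(x[:, i], x[:, j])[0, 1]
                assert d[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_constant_column_warns_and_gets_distance_one(self):
        x = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.warns(UserWarning):
            d = correlation_distance(x)
        assert d[0, 1] == 1.0 and d[1, 1] == 0.0


class TestAverageLinkage:
    def test_first_branch_separates_two_tight_pairs(self):
        d = np.array([
            [0.0, 0.1, 5.0, 5.1],
            [0.1, 0.0, 5.2, 5.0],
            [5.0, 5.2, 0.0, 0.1],
            [5.1, 5.0, 0.1, 0.0],
        ])
        dend = average_linkage(d, leaf_ids=list("abcd"))
        sides = first_branch_split(dend)
        assert sorted(map(sorted, sides)) == [["a", "b"], ["c", "d"]]

    def test_matches_scipy_reference_upgma(self, rng):
        pts = rng.normal(size=(12, 5))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ours = average_linkage(d)
        ref = sch.linkage(squareform(d, checks=False), method="average")
        assert np.allclose(sorted(ours.heights()), sorted(ref[:, 2]), atol=1e-10)
        # flat clusters at k=3 agree up to relabelling
        ours3 = cut_k(ours, 3)
        ref3 = sch.fcluster(ref, t=3, criterion="maxclust")
        pairs_ours = {(i, j) for i in range(12) for j in range(12)
                      if ours3.labels[i] == ours3.labels[j]}
        pairs_ref = {(i, j) for i in range(12) for j in range(12)
                     if ref3[i] == ref3[j]}
        assert pairs_ours == pairs_ref

    def test_leaf_input_order_invariance(self, rng):
        pts = rng.normal(size=(9, 4))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ids = [f"L{i}" for i in range(9)]
        dend1 = average_linkage(d, leaf_ids=ids)
        perm = rng.permutation(9)
        dend2 = average_linkage(d[np.ix_(perm, perm)],
                                leaf_ids=[ids[i] for i in perm])
        s1 = sorted(map(sorted, first_branch_split(dend1)))
        s2 = sorted(map(sorted, first_branch_split(dend2)))
        assert s1 == s2

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError):
            average_linkage(np.zeros((1, 1)))

    def test_nan_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError):
            average_linkage(d)

    def test_newick_export_parses(self):
        d = np.array([[0, 1, 4.0], [1, 0, 4], [4, 4, 0.0]])
        nwk = average_linkage(d, leaf_ids=["x", "y", "z"]).to_newick()
        assert nwk.endswith(";") and "x" in nwk and nwk.count("(") == 2


class TestCuts:
    @pytest.fixture()
    def dend(self, rng):
        pts = rng.normal(size=(7, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        return average_linkage(d)

    def test_k_extremes(self, dend):
        assert cut_k(dend, 1).k == 1
        assert cut_k(dend, 7).k == 7

    def test_k2_equals_first_branch(self, dend):
        cut = cut_k(dend, 2)
        sides = first_branch_split(dend)
        assert sorted(map(sorted, [cut.members(0), cut.members(1)])) == \
            sorted(map(sorted, sides))

    def test_smallest_leaf_reported_first(self, dend):
        a, _ = first_branch_split(dend)
        sides = first_branch_split(dend)
        assert min(map(str, sides[0])) < min(map(str, sides[1]))


class TestEnrichedClusterTest:
    def test_mci_majority_cluster_passes(self):
        # 24 of 29 MCI inside a 28-member cluster, 82 individuals in total
        labels = {f"M{i}": "MCI" for i in range(29)}
        labels.update({f"N{i}": "NCI" for i in range(25)})
        labels.update({f"A{i}": "AD" for i in range(28)})
        cluster = [f"M{i}" for i in range(24)] + [f"N{i}" for i in range(4)]
        passes, p = enriched_cluster_test(cluster, labels, "MCI")
        assert passes and p < 0.05

    def test_whole_cohort_cluster_fails(self):
        labels = {i: ("MCI" if i < 10 else "NCI") for i in range(30)}
        passes, p = enriched_cluster_test(list(range(30)), labels, "MCI")
        assert not passes and p == 1.0

    def test_exactly_two_thirds_fails(self):
        labels = {i: ("MCI" if i < 9 else "NCI") for i in range(40)}
        cluster = list(range(6))  # exactly 2/3 of the 9 MCI
        passes, _ = enriched_cluster_test(cluster, labels, "MCI")
        assert not passes

    def test_adding_group_member_keeps_fraction_criterion(self):
        labels = {i: ("MCI" if i < 12 else "NCI") for i in range(40)}
        cluster = list(range(9))
        passes_before, _ = enriched_cluster_test(cluster, labels, "MCI")
        passes_after, _ = enriched_cluster_test(cluster + [9], labels, "MCI")
        assert passes_before and passes_after

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            enriched_cluster_test([0], {0: "NCI"}, "MCI")


class TestKmeansElbow:
    def test_three_blobs_found(self, rng):
        pts = np.vstack([rng.normal(c, 0.3, size=(20, 2))
                         for c in ([0, 0], [6, 0], [0, 6])])
        k, cut, sse = kmeans_with_elbow(pts, range(1, 7), seed=7)
        assert k == 3 and cut.k == 3

    def test_sse_non_increasing(self, rng):
        pts = rng.normal(size=(30, 2))
        _, _, sse = kmeans_with_elbow(pts, range(1, 6), seed=1)
        values = [sse[k] for k in sorted(sse)]
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    def test_duplicate_points_reach_zero_sse(self):
        pts = np.array([[0.0], [0.0], [1.0], [1.0], [1.0]])
        _, _, sse = kmeans_with_elbow(pts, [1, 2, 3], seed=1)
        assert sse[2] == pytest.approx(0.0, abs=1e-12)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_with_elbow(np.zeros((3, 1)), [1, 4], seed=0)
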