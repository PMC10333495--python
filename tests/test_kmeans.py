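"""K-means engine: Lloyd iterations, AIC forms, and model-order selection."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from delirclust.kmeans import (
    ClusteringSolution,
    aic,
    distortion_aic,
    lloyd,
    select_k,
)


def brute_force_optimum(points, K):
    """Global minimum wcss over all partitions into exactly K nonempty sets."""
    n = len(points)
    best = math.inf
    for assign in itertools.product(range(K), repeat=n):
        if len(set(assign)) != K:
            continue
        a = np.array(assign)
        w = 0.0
        for k in range(K):
            grp = points[a == k]
            w += ((grp - grp.mean(axis=0)) ** 2).sum()
        best = min(best, w)
    return best


class TestLloyd:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 3))
        sol = lloyd(pts, K=1, seed=0)
        np.testing.assert_allclose(sol.centroids[0], pts.mean(axis=0))
        np.testing.assert_allclose(
            sol.wcss, ((pts - pts.mean(axis=0)) ** 2).sum()
        )

    def test_two_pairs_global_optimum(self):
        pts = np.array([[0, 0], [0, 1], [10, 0], [10, 1]], dtype=float)
        report = select_k(pts, k_range=[2], restarts=20, master_seed=0)
        sol = report.selected_solution
        assert sol.assignments[0] == sol.assignments[1]
        assert sol.assignments[2] == sol.assignments[3]
        assert sol.assignments[0] != sol.assignments[2]
        assert sol.wcss == pytest.approx(1.0)
        assert sol.wcss == pytest.approx(brute_force_optimum(pts, 2))

    def test_k_equals_n_zero_wcss(self):
        pts = np.arange(10, dtype=float).reshape(5, 2)
        sol = lloyd(pts, K=5, seed=3)
        assert sol.wcss == 0.0
        assert sorted(sol.assignments) == list(range(5))

    def test_invalid_arguments(self):
        pts = np.zeros((3, 2))
        with pytest.raises(ValueError):
            lloyd(pts, K=4)
        with pytest.raises(ValueError):
            lloyd(np.array([[np.nan, 0.0]]), K=1)

    @given(st.integers(0, 10_000))
    def test_wcss_monotone_over_iterations(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(30, 4))
        sol = lloyd(pts, K=4, seed=seed, collect_history=True)
        hist = sol.wcss_history
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    @given(st.integers(0, 10_000))
    def test_every_cluster_nonempty(self, seed):
        rng = np.random.default_rng(seed)
        # duplicated points provoke empty clusters at initialization
        pts = np.repeat(rng.normal(size=(4, 2)), 5, axis=0)
        sol = lloyd(pts, K=6, seed=seed)
        assert set(sol.assignments.tolist()) == set(range(6))

    def test_matches_brute_force_on_small_sets(self):
        rng = np.random.default_rng(42)
        for K in (2, 3):
            pts = rng.normal(size=(7, 2))
            opt = brute_force_optimum(pts, K)
            one = lloyd(pts, K=K, seed=1)
            assert one.wcss >= opt - 1e-9
            best = select_k(pts, k_range=[K], restarts=40, master_seed=9)
            assert best.selected_solution.wcss == pytest.approx(opt)


class TestAic:
    def test_monotone_in_wcss_at_fixed_k(self):
        s1 = ClusteringSolution(2, np.zeros(4, int), np.zeros((2, 3)), wcss=1.0)
        s2 = ClusteringSolution(2, np.zeros(4, int), np.zeros((2, 3)), wcss=2.0)
        assert aic(s1, n=4, d=3) < aic(s2, n=4, d=3)

    def test_penalty_is_2d_per_extra_cluster(self):
        s1 = ClusteringSolution(2, np.zeros(4, int), np.zeros((2, 3)), wcss=5.0)
        s2 = ClusteringSolution(3, np.zeros(4, int), np.zeros((3, 3)), wcss=5.0)
        assert aic(s2, n=4, d=3) - aic(s1, n=4, d=3) == pytest.approx(2 * 3)
        assert distortion_aic(s2, n=4, d=3) - distortion_aic(
            s1, n=4, d=3
        ) == pytest.approx(2 * 3)

    def test_profile_form_direct_evaluation(self):
        # n=4, d=2, wcss=1, K=2: 8*ln(1/8) + 8
        s = ClusteringSolution(2, np.zeros(4, int), np.zeros((2, 2)), wcss=1.0)
        assert aic(s, n=4, d=2) == pytest.approx(8 * math.log(1 / 8) + 8)
        assert aic(s, n=4, d=2) == pytest.approx(-8.63553233343869)

    def test_zero_wcss_uses_floor(self):
        s = ClusteringSolution(2, np.zeros(4, int), np.zeros((2, 2)), wcss=0.0)
        assert np.isfinite(aic(s, n=4, d=2))

    def test_nd_zero_rejected(self):
        s = ClusteringSolution(1, np.zeros(1, int), np.zeros((1, 1)), wcss=0.0)
        with pytest.raises(ValueError):
            aic(s, n=0, d=1)

    def test_relabeling_leaves_wcss_and_aic_unchanged(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(20, 3))
        sol = lloyd(pts, K=3, seed=4)
        aic(sol, *pts.shape)
        perm = sol.relabeled([2, 0, 1])
        assert perm.wcss == sol.wcss
        assert perm.aic == sol.aic
        # permuted assignment still pairs each point with the same centroid
        np.testing.assert_allclose(
            perm.centroids[perm.assignments], sol.centroids[sol.assignments]
        )


class TestSelectK:
    def blobs(self, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 0.05, size=(20, 2))
        b = rng.normal(0, 0.05, size=(20, 2)) + [8.0, 0.0]
        return np.vstack([a, b])

    def test_two_separated_blobs_select_k2(self):
        report = select_k(
            self.blobs(), k_range=range(1, 7), restarts=50, master_seed=1
        )
        assert report.selected_K == 2

    def test_deterministic_given_master_seed(self):
        pts = self.blobs(3)
        r1 = select_k(pts, k_range=range(1, 5), restarts=20, master_seed=7)
        r2 = select_k(pts, k_range=range(1, 5), restarts=20, master_seed=7)
        assert r1.selected_K == r2.selected_K
        np.testing.assert_array_equal(r1.aic_table, r2.aic_table)
        np.testing.assert_array_equal(
            r1.selected_solution.assignments, r2.selected_solution.assignments
        )

    def test_singleton_k_range(self):
        pts = self.blobs(4)
        report = select_k(pts, k_range=[3], restarts=10, master_seed=0)
        assert report.selected_K == 3

    def test_selected_is_argmin_of_recorded_table(self):
        pts = self.blobs(5)
        report = select_k(pts, k_range=range(1, 6), restarts=15, master_seed=2)
        assert report.selected_solution.aic == pytest.approx(
            np.nanmin(report.aic_table)
        )
        i = report.k_range.index(report.selected_K)
        assert np.nanmin(report.aic_table[i]) == pytest.approx(
            report.selected_solution.aic
        )

    def test_per_run_seed_replayable_in_isolation(self):
        pts = self.blobs(6)
        report = select_k(pts, k_range=range(1, 5), restarts=10, master_seed=11)
        sol = report.selected_solution
        replay = lloyd(pts, K=sol.K, seed=sol.seed)
        assert replay.wcss == pytest.approx(sol.wcss)
        np.testing.assert_array_equal(replay.assignments, sol.assignments)

    def test_report_serializes(self):
        report = select_k(self.blobs(), k_range=[1, 2], restarts=5, master_seed=0)
        d = report.to_dict()
        assert d["selected_K"] == report.selected_K
        assert set(d["best_aic_per_k"]) == {"1", "2"}
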