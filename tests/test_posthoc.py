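"""Post-hoc battery: t-tests, Bonferroni contract, ANOVA, interpretation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import delirclust as dc
from delirclust.data import DataError
from delirclust.grouping import ReducedMatrix
from delirclust.kmeans import ClusteringSolution
from delirclust.posthoc import (
    NS,
    CharacterizationConfig,
    anova_across_clusters,
    infer_roles,
    interpret_labels,
    one_sample_t,
    posthoc_profile,
)


def reduced(vals, labels=None):
    vals = np.asarray(vals, dtype=float)
    labels = labels or [f"g{j}" for j in range(vals.shape[1])]
    return ReducedMatrix(vals, [f"p{i}" for i in range(vals.shape[0])], labels)


def solution_for(assign, points):
    assign = np.asarray(assign)
    K = int(assign.max()) + 1
    centroids = np.stack([points[assign == k].mean(axis=0) for k in range(K)])
    return ClusteringSolution(K=K, assignments=assign, centroids=centroids, wcss=0.0)


class TestOneSampleT:
    def test_symmetric_sample_about_null(self):
        assert one_sample_t([1, 2, 3], 2.0) == (0.0, 1.0)

    def test_closed_form_t(self):
        t, p = one_sample_t([1, 2, 3], 0.0)
        assert t == pytest.approx(2 * math.sqrt(3))
        assert p == pytest.approx(2 * stats.t.sf(2 * math.sqrt(3), df=2))

    def test_agrees_with_scipy_to_1e10(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=rng.integers(3, 30))
            mu0 = rng.normal()
            t, p = one_sample_t(x, mu0)
            ref = stats.ttest_1samp(x, mu0)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_cases(self):
        assert one_sample_t([2.0, 2.0, 2.0], 2.0) == (0.0, 1.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            t, p = one_sample_t([2.0, 2.0, 2.0], 1.0)
        assert math.isinf(t) and t > 0 and p == 0.0

    def test_too_small_sample(self):
        with pytest.raises(DataError):
            one_sample_t([1.0], 0.0)


class TestPosthocProfile:
    def test_bonferroni_contract_both_directions(self):
        rng = np.random.default_rng(1)
        Xr = reduced(rng.normal(size=(40, 3)))
        assign = rng.integers(0, 4, size=40)
        for k in range(4):
            assign[k] = k
        profile = posthoc_profile(Xr, solution_for(assign, Xr.values))
        alpha, m = profile.config.alpha_fwer, profile.m_tests
        assert m == 4 * 3
        for k in range(4):
            for g in Xr.group_labels:
                significant = profile.direction.iloc[k][g] != NS
                assert significant == (profile.p_raw.iloc[k][g] <= alpha / m)
                if significant:
                    expected = (
                        "elevated"
                        if Xr.values[assign == k, Xr.group_labels.index(g)].mean()
                        > profile.baseline[g]
                        else "depressed"
                    )
                    assert profile.direction.iloc[k][g] == expected

    def test_huge_shift_hits_max_grade(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, size=(400, 2))
        base[:200, 0] += 10.0
        Xr = reduced(base)
        assign = np.array([0] * 200 + [1] * 200)
        profile = posthoc_profile(Xr, solution_for(assign, base))
        assert profile.direction.iloc[0]["g0"] == "elevated"
        assert profile.grade.iloc[0]["g0"] == 3
        assert profile.sign_table().iloc[0]["g0"] == "+ + +"

    def test_k1_rejected(self):
        Xr = reduced(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(DataError):
            posthoc_profile(Xr, solution_for([0] * 5, Xr.values))

    def test_reference_insomnia_archetype_profile(
        self, reference_cohort, reference_stage2
    ):
        """The sleep-only archetype's cluster: elevated on the sleep group,
        depressed on the other three."""
        Xr, pc = reference_stage2
        profile = posthoc_profile(Xr, pc.solution)
        truth = reference_cohort.truth_archetype
        # cluster holding most of archetype 5 ("insomnia")
        counts = [
            ((pc.solution.assignments == k) & (truth == 5)).sum()
            for k in range(pc.K)
        ]
        k_ins = int(np.argmax(counts))
        sleep_col = [c for c in Xr.group_labels if "sleep" in c]
        assert len(sleep_col) == 1
        row = profile.direction.iloc[k_ins]
        assert row[sleep_col[0]] == "elevated"
        for c in Xr.group_labels:
            if c != sleep_col[0]:
                assert row[c] == "depressed"


class TestAnova:
    def test_hand_computed_f(self):
        sol = solution_for([0, 0, 0, 1, 1, 1], np.zeros((6, 1)))
        F, p, dfb, dfw = anova_across_clusters([1, 2, 3, 4, 5, 6], sol)
        assert (F, dfb, dfw) == (pytest.approx(13.5), 1, 4)
        assert p == pytest.approx(stats.f.sf(13.5, 1, 4))

    def test_agrees_with_scipy_to_1e10(self):
        rng = np.random.default_rng(3)
        assign = np.repeat([0, 1, 2], [8, 12, 10])
        x = rng.normal(size=30)
        sol = solution_for(assign, np.zeros((30, 1)))
        F, p, _, _ = anova_across_clusters(x, sol)
        ref = stats.f_oneway(*(x[assign == k] for k in range(3)))
        assert F == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(4)
        assign = np.repeat([0, 1], 15)
        sol = solution_for(assign, np.zeros((30, 1)))
        ps = [
            anova_across_clusters(rng.normal(size=30), sol)[1] for _ in range(200)
        ]
        # KS against uniform; generous threshold for 200 draws
        d = stats.kstest(ps, "uniform").statistic
        assert d < 0.12

    def test_constant_covariate_rejected(self):
        sol = solution_for([0, 0, 1, 1], np.zeros((4, 1)))
        with pytest.raises(DataError, match="zero total variance"):
            anova_across_clusters([5.0, 5.0, 5.0, 5.0], sol)

    def test_small_cluster_excluded_with_warning(self):
        sol = solution_for([0, 0, 0, 1, 2, 2, 2], np.zeros((7, 1)))
        with pytest.warns(UserWarning, match="excluded"):
            F, p, dfb, dfw = anova_across_clusters([1, 2, 3, 9, 4, 5, 6], sol)
        assert dfb == 1 and dfw == 4


class TestInterpretation:
    def make_profile(self, rows):
        cols = ["motor", "cognitive", "acute", "sleep"]
        direction = pd.DataFrame(rows, columns=cols)
        K = len(rows)
        zeros = pd.DataFrame(np.zeros((K, 4)), columns=cols)
        return dc.ClusterProfile(
            t=zeros, p_raw=zeros, p_corrected=zeros, direction=direction,
            grade=zeros.astype(int), m_tests=4 * K,
            config=CharacterizationConfig(),
            baseline=pd.Series(np.zeros(4), index=cols),
        )

    def test_reference_patterns(self):
        E, D = "elevated", "depressed"
        profile = self.make_profile(
            [
                [NS, E, NS, NS],
                [E, E, E, NS],
                [NS, NS, E, NS],
                [E, E, NS, NS],
                [NS, E, NS, E],
                [D, D, D, E],
                [D, D, D, D],
            ]
        )
        labels = interpret_labels(profile)
        assert labels == [
            "cognitive and higher-order thinking domain dominant delirium",
            "prolonged delirium",
            "acute and brief delirium",
            "subsyndromal delirium-enriched",
            "subsyndromal delirium-enriched with insomnia",
            "insomnia",
            "fit",
        ]

    def test_unmatched_pattern_falls_back(self):
        E = "elevated"
        profile = self.make_profile([[E, NS, NS, E]])
        assert interpret_labels(profile) == ["unclassified pattern"]

    def test_role_inference_on_planted_partition(self):
        design = dc.default_design()
        comp = {}
        for g, name in enumerate(design.group_names):
            comp[name] = [
                c for c, gg in design.feature_partition.items() if gg == g
            ]
        roles = infer_roles(comp)
        assert roles == {
            "motor": "motor",
            "cognitive": "cognitive",
            "acute": "acute",
            "sleep": "sleep",
        }
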