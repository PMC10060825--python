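"""Inferential layer: ANOVA/ANCOVA, correlation, reliability, median split,
and bootstrap mediation, cross-checked against brute-force computations."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from driftchoice import (
    GroupStats,
    ancova_group_effect,
    cronbach_alpha,
    eta_squared,
    median_split,
    mediation_parallel,
    mediation_serial,
    mediation_simple,
    oneway_f_from_groups,
    oneway_f_from_values,
    pearson_r,
    zscore,
)
from driftchoice.cohort import CohortConfig, generate_mediation_truth


def brute_force_oneway(x1, x2):
    """Explicit sums-of-squares one-way ANOVA for two groups."""
    allv = np.concatenate([x1, x2])
    grand = allv.mean()
    ss_between = len(x1) * (x1.mean() - grand) ** 2 + len(x2) * (x2.mean() - grand) ** 2
    ss_within = ((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()
    df1, df2 = 1, len(allv) - 2
    f = (ss_between / df1) / (ss_within / df2)
    return f, scipy.stats.f.sf(f, df1, df2)


class TestOnewayF:
    def test_identical_groups_give_zero_f(self):
        g = GroupStats(10.0, 2.0, 20)
        res = oneway_f_from_groups(g, g)
        assert res.f == 0.0
        assert res.eta_sq == 0.0

    def test_hand_computed_example(self):
        res = oneway_f_from_groups(GroupStats(1.0, 1.0, 10), GroupStats(2.0, 1.0, 10))
        assert res.f == pytest.approx(5.0, rel=1e-12)

    def test_matches_brute_force_on_random_data(self, rng):
        for _ in range(20):
            x1 = rng.normal(0, 1, rng.integers(5, 30))
            x2 = rng.normal(rng.normal(), 1, rng.integers(5, 30))
            res = oneway_f_from_values(x1, x2)
            f_ref, p_ref = brute_force_oneway(x1, x2)
            assert res.f == pytest.approx(f_ref, abs=1e-10)
            assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_zero_variance_unequal_means_flagged_infinite(self):
        res = oneway_f_from_groups(GroupStats(1.0, 0.0, 5), GroupStats(2.0, 0.0, 5))
        assert np.isinf(res.f)


class TestEtaSquared:
    def test_definition_and_zero(self):
        assert eta_squared(0.0, 1, 70) == 0.0
        f = 12.5
        assert eta_squared(f, 1, 70) == pytest.approx(f / (f + 70))

    def test_consistent_with_oneway_result(self, rng):
        x1, x2 = rng.normal(0, 1, 15), rng.normal(1, 1, 12)
        res = oneway_f_from_values(x1, x2)
        assert res.eta_sq == pytest.approx(eta_squared(res.f, res.df1, res.df2))


class TestAncova:
    def test_reduces_to_oneway_without_covariates(self, rng):
        y = rng.normal(0, 1, 40)
        group = np.repeat(["a", "b"], 20)
        anc = ancova_group_effect(y, group)
        one = oneway_f_from_values(y[group == "a"], y[group == "b"])
        assert anc.f == pytest.approx(one.f, rel=1e-9)
        assert anc.p == pytest.approx(one.p, rel=1e-9)

    def test_group_aliased_covariate_raises(self, rng):
        y = rng.normal(0, 1, 30)
        group = np.repeat(["a", "b"], 15)
        cov = pd.DataFrame({"copy_of_group": (group == "b").astype(float)})
        with pytest.raises(ValueError, match="copy_of_group"):
            ancova_group_effect(y, group, cov)

    def test_noise_covariates_leave_f_close(self, rng):
        n = 72
        group = np.repeat(["ctl", "sep"], n // 2)
        diffs = []
        for _ in range(20):
            y = rng.normal(0, 1, n) + 0.8 * (group == "sep")
            cov = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=list("pqr"))
            f_adj = ancova_group_effect(y, group, cov).f
            f_raw = ancova_group_effect(y, group).f
            diffs.append(f_adj / f_raw)
        assert np.median(diffs) == pytest.approx(1.0, abs=0.25)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_hand_computed_value(self):
        r, _ = pearson_r([1.0, 2.0, 3.0], [1.0, 2.0, 2.0])
        assert r == pytest.approx(np.sqrt(3) / 2, rel=1e-12)

    def test_null_correlation_small(self, rng):
        x, y = rng.normal(0, 1, 1000), rng.normal(0, 1, 1000)
        r, _ = pearson_r(x, y)
        assert abs(r) < 0.1

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCronbachAlpha:
    def test_duplicated_items_give_one(self, rng):
        col = rng.normal(0, 1, 50)
        assert cronbach_alpha(np.column_stack([col] * 5)) == pytest.approx(1.0)

    def test_independent_items_near_zero(self, rng):
        alphas = [cronbach_alpha(rng.normal(0, 1, (500, 10))) for _ in range(10)]
        assert abs(np.mean(alphas)) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((10, 3)))


class TestMedianSplit:
    def test_split_at_median_33(self):
        scores = np.array([30, 31, 33, 33, 35, 36.0])
        labels, med = median_split(scores)
        assert med == 33.0
        assert list(labels) == ["low", "low", "low", "low", "high", "high"]

    def test_even_series(self):
        labels, med = median_split([1.0, 2.0, 3.0, 4.0])
        assert med == 2.5
        assert list(labels) == ["low", "low", "high", "high"]

    def test_all_equal_warns(self):
        with pytest.warns(UserWarning):
            median_split([5.0, 5.0, 5.0])


class TestMediation:
    def test_null_final_path_centered_at_zero(self, rng):
        n = 200
        x = rng.normal(0, 1, n)
        m = 0.5 * x + rng.normal(0, 1, n)
        y = 0.3 * x + rng.normal(0, 1, n)  # independent of m given x
        res = mediation_simple(x, m, y, n_boot=2000, rng_seed=1)
        assert abs(res.indirect) < 2 * res.boot_se
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_simple_recovery_at_study_scale(self):
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 113)
            m = 0.5 * x + rng.normal(0, 1, 113)
            y = 0.4 * m + rng.normal(0, 1, 113)
            res = mediation_simple(x, m, y, n_boot=400, rng_seed=seed)
            estimates.append(res.indirect)
        assert np.mean(estimates) == pytest.approx(0.2, abs=0.05)

    def test_seeded_determinism(self, rng):
        x, m, y = rng.normal(0, 1, (3, 60))
        a = mediation_simple(x, m, y, n_boot=500, rng_seed=42)
        b = mediation_simple(x, m, y, n_boot=500, rng_seed=42)
        assert (a.ci_low, a.ci_high, a.boot_se) == (b.ci_low, b.ci_high, b.boot_se)

    def test_serial_truth_bookkeeping_and_recovery(self):
        data, truth = generate_mediation_truth(CohortConfig(seed=5), n=400)
        assert truth["indirect_serial"] == pytest.approx(0.6 * 0.5 * 0.4)
        res = mediation_serial(data.x, data.m1, data.m2, data.y, n_boot=1000, rng_seed=3)
        assert res.indirect == pytest.approx(truth["indirect_serial"], abs=0.05)
        assert res.ci_low <= truth["indirect_serial"] <= res.ci_high

    def test_serial_zero_path_zero_indirect(self, rng):
        n = 300
        x = rng.normal(0, 1, n)
        m1 = 0.6 * x + rng.normal(0, 1, n)
        m2 = rng.normal(0, 1, n)  # m1 -> m2 path absent
        y = 0.4 * m2 + rng.normal(0, 1, n)
        res = mediation_serial(x, m1, m2, y, n_boot=800, rng_seed=2)
        assert abs(res.indirect) < 0.05

    def test_ci_width_shrinks_with_sample_size(self):
        widths = {}
        for n in (50, 200, 800):
            rng = np.random.default_rng(n)
            x = rng.normal(0, 1, n)
            m = 0.5 * x + rng.normal(0, 1, n)
            y = 0.4 * m + rng.normal(0, 1, n)
            res = mediation_simple(x, m, y, n_boot=1500, rng_seed=n)
            widths[n] = res.ci_high - res.ci_low
        assert widths[50] > widths[200] > widths[800]
        assert widths[50] / widths[200] == pytest.approx(2.0, abs=0.7)
        assert widths[200] / widths[800] == pytest.approx(2.0, abs=0.7)

    def test_parallel_identifies_active_mediator(self, rng):
        n = 300
        x = rng.normal(0, 1, n)
        m_active = 0.6 * x + rng.normal(0, 1, n)
        m_inert = 0.5 * x + rng.normal(0, 1, n)  # correlated with x, no effect on y
        y = 0.5 * m_active + rng.normal(0, 1, n)
        out = mediation_parallel(x, {"active": m_active, "inert": m_inert}, y,
                                 n_boot=800, rng_seed=4)
        assert out["active"].ci_low > 0.0
        assert out["inert"].ci_low <= 0.0 <= out["inert"].ci_high

    def test_too_small_sample_rejected(self, rng):
        x, m, y = rng.normal(0, 1, (3, 5))
        with pytest.raises(ValueError):
            mediation_simple(x, m, y)

    def test_zscore_uses_sample_sd(self):
        z = zscore([20.0, 40.0])
        np.testing.assert_allclose(np.abs(z), 1 / np.sqrt(2))
        with pytest.raises(ValueError):
            zscore([3.0, 3.0])
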