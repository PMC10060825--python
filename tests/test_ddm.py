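"""Diffusion core: drift construction, absorption probability, first-passage
density, simulator agreement, and likelihood arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.integrate import quad

from driftchoice import ChoicePair, DDMParams, TrialRecord, choice_probability, drift_rate, wfpt_density
from driftchoice.ddm import (
    _fpt_std_large,
    _fpt_std_small,
    negative_log_likelihood,
    simulate_first_passage,
    simulate_trials,
)

ANCHOR_PAIR = ChoicePair(amount_ss=17.0, delay_ss=0.0, amount_ll=38.0, delay_ll=30.0)


class TestChoicePair:
    def test_attribute_differences(self):
        assert ANCHOR_PAIR.money_diff == 21.0
        assert ANCHOR_PAIR.delay_diff == 30.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(amount_ss=38.0, delay_ss=0.0, amount_ll=17.0, delay_ll=30.0),  # SS richer
            dict(amount_ss=17.0, delay_ss=30.0, amount_ll=38.0, delay_ll=30.0),  # no extra delay
            dict(amount_ss=-1.0, delay_ss=0.0, amount_ll=38.0, delay_ll=30.0),
        ],
    )
    def test_invalid_pairs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ChoicePair(**kwargs)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DDMParams(z=0.0)
        with pytest.raises(ValueError):
            DDMParams(a=-1.0)
        with pytest.raises(ValueError):
            DDMParams(s=0.0)


class TestDriftRate:
    @pytest.mark.parametrize(
        "dc,wm,wd,expected",
        [
            (0.0, 0.047, -0.009, 0.047 * 21 - 0.009 * 30),  # reported control-group weights
            (0.0, 0.0, 0.0, 0.0),
            (0.1, 0.0, 0.0, 0.1),
        ],
    )
    def test_linear_attribute_combination(self, dc, wm, wd, expected):
        params = DDMParams(dc=dc, wm=wm, wd=wd)
        assert drift_rate(params, ANCHOR_PAIR) == pytest.approx(expected, abs=1e-12)


class TestChoiceProbability:
    def test_no_drift_returns_starting_fraction(self):
        assert choice_probability(0.0, 2.0, 0.5) == pytest.approx(0.5)
        assert choice_probability(0.0, 1.0, 0.3) == pytest.approx(0.3)

    def test_closed_form_value(self):
        expected = (1 - math.exp(-2)) / (1 - math.exp(-4))
        assert choice_probability(1.0, 2.0, 0.5) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.8808, abs=1e-4)

    def test_extreme_drift_saturates_boundedly(self):
        assert choice_probability(1e6, 1.0, 0.5) == pytest.approx(1.0)
        assert choice_probability(-1e6, 1.0, 0.5) == pytest.approx(0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        v=hst.floats(-5, 5),
        a=hst.floats(0.2, 4.0),
        z=hst.floats(0.05, 0.95),
    )
    def test_bounded_and_monotone_in_v(self, v, a, z):
        p = choice_probability(v, a, z)
        assert 0.0 <= p <= 1.0
        assert choice_probability(v + 0.1, a, z) >= p

    def test_monotone_in_z(self):
        zs = np.linspace(0.1, 0.9, 17)
        for v in (-1.0, 0.0, 1.5):
            ps = choice_probability(np.full_like(zs, v), 1.5, zs)
            assert np.all(np.diff(ps) > 0)

    def test_scale_invariance(self):
        # (v, a, s) -> (c v, c a, c s) leaves the absorption probability alone
        for c in (0.1, 3.0):
            assert choice_probability(0.7, 1.8, 0.4, 1.0) == pytest.approx(
                choice_probability(0.7 * c, 1.8 * c, 0.4, c), rel=1e-10
            )


class TestWfptDensity:
    def test_rejects_nonpositive_time(self):
        with pytest.raises(ValueError):
            wfpt_density(0.0, 1.0, 1.5, 0.5)

    def test_symmetry_without_drift(self):
        t = np.linspace(0.05, 3.0, 40)
        up = wfpt_density(t, 0.0, 1.5, 0.5, 1.0, "upper")
        lo = wfpt_density(t, 0.0, 1.5, 0.5, 1.0, "lower")
        np.testing.assert_allclose(up, lo, rtol=1e-10)

    @pytest.mark.parametrize("v,a,z", [(0.5, 1.5, 0.5), (2.0, 0.5, 0.2), (-1.0, 3.0, 0.8)])
    def test_normalization_and_upper_mass(self, v, a, z):
        up = quad(lambda t: wfpt_density(t, v, a, z, 1.0, "upper"), 1e-9, 300, limit=200)[0]
        lo = quad(lambda t: wfpt_density(t, v, a, z, 1.0, "lower"), 1e-9, 300, limit=200)[0]
        assert up + lo == pytest.approx(1.0, abs=1e-4)
        assert up == pytest.approx(choice_probability(v, a, z), abs=1e-6)

    def test_small_and_large_time_series_agree(self):
        # both expansions evaluated far past their switch point with many terms
        v, a, w = 0.5, 1.5, 0.5
        for t in (0.2, 0.4, 0.8, 1.5):
            tt = np.array([t / a**2])
            ww = np.array([w])
            small = _fpt_std_small(tt, ww, 80)[0]
            large = _fpt_std_large(tt, ww, 80)[0]
            assert small == pytest.approx(large, abs=1e-8)

    def test_time_rescaling_of_density(self):
        # densities transform with the same (v, a, s) -> (c v, c a, c s) scaling
        c = 2.0
        t = np.linspace(0.1, 2.0, 15)
        base = wfpt_density(t, 0.8, 1.5, 0.4, 1.0, "upper")
        scaled = wfpt_density(t, 0.8 * c, 1.5 * c, 0.4, c, "upper")
        np.testing.assert_allclose(base, scaled, rtol=1e-9)


class TestSimulator:
    def test_rt_floored_by_nondecision_time(self, menu):
        params = DDMParams(z=0.5, a=1.0, t0=0.3, dc=0.5)
        trials = simulate_trials(params, menu[:40], rng=1)
        assert all(t.rt >= 0.3 for t in trials)

    def test_dominant_drift_forces_delayed_choice(self):
        upper, _, _ = simulate_first_passage(10.0, 1.0, 0.5, n=10_000, rng=2)
        assert upper.mean() >= 0.99

    def test_choice_fraction_matches_analytic(self):
        n = 100_000
        upper, _, _ = simulate_first_passage(1.0, 2.0, 0.5, n=n, rng=3)
        p = choice_probability(1.0, 2.0, 0.5)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(upper.mean() - p) <= 3 * se

    def test_mean_passage_time_matches_theory(self):
        # zero drift from the midpoint: E[T] = z(1-z) a^2 / s^2
        upper, t, cens = simulate_first_passage(0.0, 1.5, 0.5, n=40_000, rng=4)
        assert not cens.any()
        assert t.mean() == pytest.approx(0.25 * 1.5**2, rel=0.03)

    def test_seeded_determinism(self):
        a = simulate_first_passage(0.5, 1.5, 0.5, n=500, rng=9)
        b = simulate_first_passage(0.5, 1.5, 0.5, n=500, rng=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestLikelihood:
    def _one_trial(self):
        return TrialRecord(pair=ANCHOR_PAIR, choice="LL", rt=0.9)

    def test_single_trial_is_negative_log_density(self, typical_params):
        trial = self._one_trial()
        v = drift_rate(typical_params, trial.pair)
        dens = wfpt_density(trial.rt - typical_params.t0, v, typical_params.a,
                            typical_params.z, boundary="upper")
        assert negative_log_likelihood(typical_params, [trial]) == pytest.approx(-math.log(dens))

    def test_additivity_on_duplicated_trials(self, typical_params):
        trial = self._one_trial()
        nll1 = negative_log_likelihood(typical_params, [trial])
        nll2 = negative_log_likelihood(typical_params, [trial, trial])
        assert nll2 == pytest.approx(2 * nll1)

    def test_empty_trial_list_rejected(self, typical_params):
        with pytest.raises(ValueError):
            negative_log_likelihood(typical_params, [])

    def test_rt_below_t0_floored_not_infinite(self):
        params = DDMParams(t0=1.0)
        trial = TrialRecord(pair=ANCHOR_PAIR, choice="SS", rt=0.5)
        nll = negative_log_likelihood(params, [trial])
        assert math.isfinite(nll)
        assert nll == pytest.approx(-math.log(1e-12))

    def test_true_params_beat_perturbed_threshold(self, menu, typical_params):
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            trials = simulate_trials(typical_params, menu * 2, rng=100 + seed)
            nll_true = negative_log_likelihood(typical_params, trials)
            worse = DDMParams(z=typical_params.z, a=typical_params.a * 1.5,
                              t0=typical_params.t0, dc=typical_params.dc,
                              wm=typical_params.wm, wd=typical_params.wd)
            wins += negative_log_likelihood(worse, trials) > nll_true
        assert wins >= 0.95 * n_rep
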