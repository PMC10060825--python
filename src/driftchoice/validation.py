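"""Validation experiments: oracle agreement, recovery, and calibration.

These are the package's standing quality checks, each run end to end from
fresh synthetic data:

* printed-statistic reproduction (deterministic desk check of the ANOVA
  layer against the emulated studies' published summary numbers);
* simulator-vs-analytic agreement of the diffusion core on a parameter
  grid, plus first-passage density normalization;
* decision-weight recovery: simulate cohorts with two known money-weight
  distributions, refit every participant, and measure rank correlation and
  the power of the group contrast;
* mediation recovery and calibration of the percentile-bootstrap interval
  (bias of the serial indirect effect, CI coverage, null rejection rate).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.stats import spearmanr

from . import stats as st
from .cohort import (
    CohortConfig,
    _draw_params,
    _simulate_participant_trials,
    generate_choice_menu,
    generate_mediation_truth,
)
from .ddm import choice_probability, simulate_first_passage, wfpt_density
from .inference import fit_individual
from .pipeline import reproduce_printed_statistics

__all__ = [
    "ddm_oracle_check",
    "density_normalization_check",
    "weight_recovery_experiment",
    "mediation_calibration",
    "reproduce_printed_statistics",
]

ORACLE_GRID = {
    "a": (0.5, 1.5, 3.0),
    "v": (-2.0, 0.0, 2.0),
    "z": (0.2, 0.5, 0.8),
}


def ddm_oracle_check(n: int = 100_000, seed: int = 0, grid: dict | None = None,
                     dt: float = 0.001) -> pd.DataFrame:
    """Simulated choice fractions vs the closed-form absorption probability.

    For every (a, v, z) grid cell, simulates ``n`` first passages and reports
    the empirical upper-boundary fraction, the analytic probability, and the
    discrepancy in binomial standard errors.
    """
    grid = grid or ORACLE_GRID
    rng = np.random.default_rng(seed)
    rows = []
    for a in grid["a"]:
        for v in grid["v"]:
            for z in grid["z"]:
                upper, _, _ = simulate_first_passage(v, a, z, 1.0, n=n, rng=rng, dt=dt)
                p = choice_probability(v, a, z, 1.0)
                se = max(np.sqrt(p * (1 - p) / n), 1.0 / n)
                rows.append(
                    {"a": a, "v": v, "z": z, "p_analytic": p,
                     "p_simulated": float(upper.mean()),
                     "z_score": (float(upper.mean()) - p) / se, "n": n}
                )
    return pd.DataFrame(rows)


def density_normalization_check(grid: dict | None = None) -> pd.DataFrame:
    """Numeric integral of upper + lower first-passage densities per grid cell."""
    grid = grid or ORACLE_GRID
    rows = []
    for a in grid["a"]:
        for v in grid["v"]:
            for z in grid["z"]:
                up = quad(lambda t: wfpt_density(t, v, a, z, 1.0, "upper"), 1e-9, 300, limit=200)[0]
                lo = quad(lambda t: wfpt_density(t, v, a, z, 1.0, "lower"), 1e-9, 300, limit=200)[0]
                rows.append(
                    {"a": a, "v": v, "z": z, "total_mass": up + lo,
                     "upper_mass": up, "p_analytic": choice_probability(v, a, z, 1.0)}
                )
    return pd.DataFrame(rows)


def weight_recovery_experiment(
    n_replicates: int = 20,
    n_per_group: int = 36,
    n_trials: int = 200,
    seed: int = 0,
    config: CohortConfig | None = None,
) -> dict:
    """Money-weight recovery at the emulated studies' effect size.

    Each replicate draws ``n_per_group`` participants per group with true
    money weights from the two reported group distributions (0.047/0.029 vs
    0.023/0.026), simulates ``n_trials`` choices each, refits every
    participant by maximum likelihood, and records (i) the Spearman rank
    correlation between true and recovered weights and (ii) whether the
    one-way group contrast on recovered weights rejects at alpha = 0.05.
    """
    config = config or CohortConfig()
    menu = generate_choice_menu(config)
    rank_corrs = []
    rejections = []
    rng = np.random.default_rng(seed)
    for rep in range(n_replicates):
        true_wm, est_wm, groups = [], [], []
        for group in ("control", "separated"):
            for _ in range(n_per_group):
                params = _draw_params(rng, config, group)
                trials = _simulate_participant_trials(rng, params, menu, n_trials, config.sim_dt)
                fit = fit_individual(trials, rng_seed=int(rng.integers(2**31 - 1)))
                true_wm.append(params.wm)
                est_wm.append(fit.params.wm)
                groups.append(group)
        groups = np.array(groups)
        est_wm = np.array(est_wm)
        rank_corrs.append(float(spearmanr(true_wm, est_wm).statistic))
        contrast = st.oneway_f_from_values(
            est_wm[groups == "control"], est_wm[groups == "separated"]
        )
        rejections.append(contrast.p < 0.05)
    return {
        "rank_corr_mean": float(np.mean(rank_corrs)),
        "rank_corr_min": float(np.min(rank_corrs)),
        "rejection_rate": float(np.mean(rejections)),
        "n_replicates": n_replicates,
        "n_per_group": n_per_group,
        "n_trials": n_trials,
    }


def mediation_calibration(
    seed: int = 0,
    n: int = 72,
    n_recovery: int = 50,
    n_coverage: int = 200,
    n_boot: int = 5000,
) -> dict:
    """Serial-mediation recovery, CI coverage, and null rejection rate.

    * recovery: ``n_recovery`` datasets from the default chain (a1 = 0.6,
      d21 = 0.5, b2 = 0.4, serial indirect 0.12) at sample size ``n``; the
      mean estimated indirect is compared with truth;
    * coverage: ``n_coverage`` datasets split between that alternative chain
      and a final-path-null chain; fraction of 95% percentile CIs containing
      the true serial indirect;
    * null rejection: rate at which the CI excludes zero when the final path
      b2 is zero (the bootstrap test's size at the null).
    """
    rng = np.random.default_rng(seed)
    alt_cfg = CohortConfig()
    null_cfg = CohortConfig(
        mediation_paths={"a1": 0.6, "d21": 0.5, "b2": 0.0, "a2": 0.0, "b1": 0.0, "c_prime": 0.2}
    )

    estimates = []
    for _ in range(n_recovery):
        data, truth = generate_mediation_truth(alt_cfg, n=n, rng_seed=int(rng.integers(2**31 - 1)))
        res = st.mediation_serial(data.x, data.m1, data.m2, data.y, n_boot=n_boot,
                                  rng_seed=int(rng.integers(2**31 - 1)))
        estimates.append(res.indirect)
    truth_alt = truth["indirect_serial"]

    covered = []
    null_rejections = []
    for i in range(n_coverage):
        cfg = alt_cfg if i % 2 == 0 else null_cfg
        data, truth_i = generate_mediation_truth(cfg, n=n, rng_seed=int(rng.integers(2**31 - 1)))
        res = st.mediation_serial(data.x, data.m1, data.m2, data.y, n_boot=n_boot,
                                  rng_seed=int(rng.integers(2**31 - 1)))
        covered.append(res.ci_low <= truth_i["indirect_serial"] <= res.ci_high)
        if i % 2 == 1:
            null_rejections.append(not (res.ci_low <= 0.0 <= res.ci_high))

    return {
        "indirect_truth": float(truth_alt),
        "indirect_mean": float(np.mean(estimates)),
        "indirect_bias": float(np.mean(estimates) - truth_alt),
        "ci_coverage": float(np.mean(covered)),
        "null_rejection_rate": float(np.mean(null_rejections)),
        "n": n,
        "n_recovery": n_recovery,
        "n_coverage": n_coverage,
        "n_boot": n_boot,
    }
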