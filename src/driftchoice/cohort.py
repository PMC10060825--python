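"""Synthetic study-shaped cohorts with known ground truth.

Generates complete datasets shaped like the four studies of the smartphone
separation / intertemporal choice design, so every downstream stage (task
scoring, diffusion fitting, group statistics, mediation) can be exercised
and validated against latent truth without any external data:

* a binary-choice cohort (control vs. smartphone separation, or an
  addiction median-split cohort) with per-participant latent diffusion
  parameters, simulated trials, item-level smartphone-addiction-scale (SAS)
  responses tuned to a target Cronbach alpha, state/trait anxiety scores
  with a group-specific SAS correlation, and purchase-scenario responses;
* a titration cohort with latent hyperbolic discount rates and logistic
  response noise;
* linear-Gaussian serial mediation data with known path coefficients.

Default parameter values are the group means/SDs reported for the emulated
studies; everything is driven by a single seeded Generator so cohorts are
byte-identical under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .ddm import ChoicePair, DDMParams, TrialRecord, drift_rates, simulate_first_passage
from .tasks import (
    DEFAULT_DELAY_DAYS,
    DEFAULT_DELAYED_AMOUNT,
    DEFAULT_GRID,
    ScenarioResponses,
    TitrationSeries,
    hyperbolic_value,
)

__all__ = [
    "CohortConfig",
    "ParticipantRecord",
    "generate_choice_menu",
    "generate_cohort",
    "generate_titration_cohort",
    "generate_mediation_truth",
    "participants_to_frame",
    "truth_to_frame",
    "sas_items_matrix",
]

GROUPS = ("control", "separated")


def _group_dict(control, separated):
    return {"control": control, "separated": separated}


@dataclass
class CohortConfig:
    """Every generator default, explicit and serializable.

    Group-level means/SDs default to the emulated studies' reported values:
    decision weight on the money difference 0.047 (SD 0.029) in the control
    group vs 0.023 (SD 0.026) under separation; weight on the delay
    difference -0.009/-0.010 (SD 0.002); state anxiety 29.11 (4.23) vs
    37.50 (7.25) with no group difference in trait anxiety beyond the
    printed means; SAS totals in 11-55 with target alpha 0.80 and a
    SAS-state-anxiety correlation of 0.414 in the separation group only.
    """

    n_per_group: int = 36
    seed: int = 0
    n_trials: int = 80

    # latent diffusion parameter distributions, per group: (mean, sd)
    wm: dict = field(default_factory=lambda: _group_dict((0.047, 0.029), (0.023, 0.026)))
    wd: dict = field(default_factory=lambda: _group_dict((-0.009, 0.002), (-0.010, 0.002)))
    dc: dict = field(default_factory=lambda: _group_dict((0.05, 0.10), (0.05, 0.10)))
    a: tuple = (1.8, 0.3)
    t0: tuple = (0.35, 0.08)
    z: tuple = (0.5, 0.05)
    # truncation boxes for the latent draws (resampled, not clipped)
    a_range: tuple = (0.6, 3.2)
    t0_range: tuple = (0.1, 0.8)
    z_range: tuple = (0.2, 0.8)

    # questionnaire models: (mean, sd) per group
    state_anxiety: dict = field(default_factory=lambda: _group_dict((29.11, 4.23), (37.50, 7.25)))
    trait_anxiety: dict = field(default_factory=lambda: _group_dict((31.78, 3.78), (32.83, 4.35)))
    stai_range: tuple = (20.0, 80.0)
    sas_total: dict = field(default_factory=lambda: _group_dict((34.86, 2.75), (33.58, 2.83)))
    sas_items: int = 11
    sas_item_range: tuple = (1.0, 5.0)
    sas_alpha_target: float = 0.80
    sas_state_corr: dict = field(default_factory=lambda: _group_dict(0.0, 0.414))

    # purchase scenarios: (mean, sd) per group
    restaurant: dict = field(default_factory=lambda: _group_dict((29.89, 14.41), (24.06, 12.59)))
    movie: dict = field(default_factory=lambda: _group_dict((87.75, 17.72), (80.72, 29.36)))
    gift: dict = field(default_factory=lambda: _group_dict((26.0, 13.0), (26.0, 13.0)))

    # addiction-design (median-split) cohort
    n_addiction: int = 113
    addiction_sas: tuple = (33.0, 3.0)
    extended_self_base: tuple = (4.3, 0.85)  # intercept-ish mean, residual sd
    extended_self_slope: float = 0.55  # per SD of SAS
    fomo_base: tuple = (2.94, 0.50)
    fomo_slope: float = 0.24
    social_threat_base: tuple = (3.0, 0.75)
    social_threat_slope: float = 0.20
    anxiety_on_extended_self: float = 0.45  # 1-5 anxiety scale per Venn point
    anxiety_base: tuple = (1.2, 0.85)
    anxiety_range: tuple = (1.0, 5.0)

    # titration (study-1/2 shaped) cohort
    n_titration: int = 185
    log_k_mean: float = math.log(0.010)  # median k = 0.010 per day
    log_k_sd: float = 0.7
    titration_noise: float = 8.0  # logistic temperature, currency units (0 = deterministic)

    # trial menu: immediate amounts x money differences x delays
    menu_amount_ss: tuple = (10.0, 14.0, 17.0, 20.0, 25.0)
    menu_money_diff: tuple = (6.0, 11.0, 16.0, 21.0)
    menu_delay_ll: tuple = (10.0, 20.0, 30.0, 60.0)

    # mediation truth harness
    mediation_paths: dict = field(
        default_factory=lambda: {"a1": 0.6, "d21": 0.5, "b2": 0.4, "a2": 0.0, "b1": 0.0, "c_prime": 0.2}
    )
    mediation_noise_sd: float = 1.0

    sim_dt: float = 0.001

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)


@dataclass
class ParticipantRecord:
    """Container for one synthetic participant, latent truth included."""

    id: int
    group: str
    sas_total: float
    stai_state: float
    stai_trait: float
    scenarios: ScenarioResponses
    sas_item_scores: np.ndarray
    extended_self: float = float("nan")
    fomo_mean: float = float("nan")
    social_threat_mean: float = float("nan")
    true_params: DDMParams | None = None
    trials: list = field(default_factory=list)
    titration: TitrationSeries | None = None
    true_k: float = float("nan")
    # demographics (noise covariates for the covariate-adjusted contrasts)
    gender: int = 0
    age: float = 25.0
    education: str = "bachelor"
    job: str = "student"
    income: float = 5000.0


def _trunc_normal(rng: np.random.Generator, mean, sd, lo, hi, size=None):
    """Gaussian draws truncated to [lo, hi] by resampling (no boundary spikes)."""
    out = rng.normal(mean, sd, size=size)
    scalar = np.ndim(out) == 0
    out = np.atleast_1d(out)
    for _ in range(1000):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    else:
        raise RuntimeError("truncated sampling failed; range too far from mean")
    return float(out[0]) if scalar else out


def generate_choice_menu(config: CohortConfig | None = None) -> list[ChoicePair]:
    """Deterministic intertemporal-choice menu (default 80 pairs).

    Crosses immediate amounts, money differences, and delays on the scale of
    the task's worked example; the ($17 today vs $38 in 30 days) anchor pair
    is a member of the default cross.
    """
    config = config or CohortConfig()
    menu = [
        ChoicePair(amount_ss=ss, delay_ss=0.0, amount_ll=ss + md, delay_ll=dl)
        for ss in config.menu_amount_ss
        for md in config.menu_money_diff
        for dl in config.menu_delay_ll
    ]
    return menu


def _sas_item_model(config: CohortConfig) -> tuple[float, float]:
    """Scaling constants of the parallel-items SAS model.

    Items are c*(theta + eps_i) + item mean, eps_i iid with variance chosen
    so the expected Cronbach alpha equals the target: the mean inter-item
    correlation must be rbar = alpha / (k - (k-1) alpha), so
    var(eps) = (1 - rbar)/rbar for a unit-variance trait theta.
    Returns (var_eps, attenuation) where attenuation = corr(total, theta)
    = sqrt(alpha) (Spearman-Brown).
    """
    k = config.sas_items
    alpha = config.sas_alpha_target
    rbar = alpha / (k - (k - 1) * alpha)
    var_eps = (1.0 - rbar) / rbar
    atten = k / math.sqrt(k * k + k * var_eps)
    return var_eps, atten


def _sas_items_from_theta(
    rng: np.random.Generator, theta: np.ndarray, total_mean: float, total_sd: float,
    config: CohortConfig,
) -> np.ndarray:
    """Item-level SAS responses with the configured total mean/SD and alpha."""
    k = config.sas_items
    var_eps = _sas_item_model(config)[0]
    eps = rng.normal(0.0, math.sqrt(var_eps), size=(len(theta), k))
    scale = total_sd / math.sqrt(k * k + k * var_eps)
    items = total_mean / k + scale * (theta[:, None] + eps)
    lo, hi = config.sas_item_range
    return np.clip(items, lo, hi)


def _correlated_pair(rng: np.random.Generator, r: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    if not (-1.0 <= r <= 1.0):
        raise ValueError(f"correlation {r} outside [-1, 1]")
    u = rng.standard_normal(n)
    w = rng.standard_normal(n)
    return u, r * u + math.sqrt(1.0 - r * r) * w


def _draw_params(rng: np.random.Generator, config: CohortConfig, group: str) -> DDMParams:
    wm_m, wm_s = config.wm[group]
    wd_m, wd_s = config.wd[group]
    dc_m, dc_s = config.dc[group]
    return DDMParams(
        z=_trunc_normal(rng, *config.z, *config.z_range),
        a=_trunc_normal(rng, *config.a, *config.a_range),
        t0=_trunc_normal(rng, *config.t0, *config.t0_range),
        dc=rng.normal(dc_m, dc_s),
        wm=rng.normal(wm_m, wm_s),
        wd=rng.normal(wd_m, wd_s),
    )


def _simulate_participant_trials(
    rng: np.random.Generator, params: DDMParams, menu: Sequence[ChoicePair],
    n_trials: int, dt: float,
) -> list[TrialRecord]:
    reps = -(-n_trials // len(menu))  # ceil
    pairs = (list(menu) * reps)[:n_trials]
    md = np.array([p.money_diff for p in pairs])
    dd = np.array([p.delay_diff for p in pairs])
    v = drift_rates(params, md, dd)
    upper, tdec, cens = simulate_first_passage(v, params.a, params.z, params.s, rng=rng, dt=dt)
    return [
        TrialRecord(pair=p, choice="LL" if up else "SS", rt=float(t + params.t0), censored=bool(c))
        for p, up, t, c in zip(pairs, upper, tdec, cens)
    ]


def _demographics(rng: np.random.Generator) -> dict:
    return {
        "gender": int(rng.integers(0, 2)),
        "age": float(np.round(rng.uniform(20, 35), 0)),
        "education": str(rng.choice(["college", "bachelor", "master"])),
        "job": str(rng.choice(["student", "technical", "manager"])),
        "income": float(np.round(rng.normal(6000, 1500), -2)),
    }


def generate_cohort(config: CohortConfig | None = None, design: str = "separation") -> list[ParticipantRecord]:
    """Full binary-choice cohort with latent truth.

    ``design='separation'``: two groups (control / separated) of
    ``n_per_group`` with group-specific diffusion weights, anxiety, SAS, and
    scenario distributions; SAS totals correlate with state anxiety at the
    configured group-specific r (0.414 under separation, 0 in control).

    ``design='addiction'``: one sample of ``n_addiction`` labelled high/low
    by a median split on SAS, with extended-self the true mediator between
    addiction and anxiety and FoMO / social threat correlated with SAS but
    causally inert.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    menu = generate_choice_menu(config)
    if design == "separation":
        return _generate_separation(config, rng, menu)
    if design == "addiction":
        return _generate_addiction(config, rng)
    raise ValueError(f"design must be 'separation' or 'addiction', got {design!r}")


def _generate_separation(config: CohortConfig, rng: np.random.Generator,
                         menu: Sequence[ChoicePair]) -> list[ParticipantRecord]:
    records = []
    pid = 0
    _, atten = _sas_item_model(config)
    for group in GROUPS:
        n = config.n_per_group
        r_total = config.sas_state_corr[group]
        r_latent = r_total / atten
        if abs(r_latent) > 1.0:
            raise ValueError(
                f"target SAS-anxiety correlation {r_total} infeasible at alpha "
                f"{config.sas_alpha_target} (latent r would be {r_latent:.3f})"
            )
        theta, anx_z = _correlated_pair(rng, r_latent, n)
        sas_mean, sas_sd = config.sas_total[group]
        items = _sas_items_from_theta(rng, theta, sas_mean, sas_sd, config)
        st_m, st_s = config.state_anxiety[group]
        lo, hi = config.stai_range
        state = np.clip(st_m + st_s * anx_z, lo, hi)
        trait = _trunc_normal(rng, *config.trait_anxiety[group], lo, hi, size=n)
        rest = _trunc_normal(rng, *config.restaurant[group], 5, 60, size=n)
        movie = _trunc_normal(rng, *config.movie[group], 1, 100, size=n)
        gift = _trunc_normal(rng, *config.gift[group], 1, 50, size=n)
        for i in range(n):
            params = _draw_params(rng, config, group)
            trials = _simulate_participant_trials(rng, params, menu, config.n_trials, config.sim_dt)
            records.append(
                ParticipantRecord(
                    id=pid,
                    group=group,
                    sas_total=float(items[i].sum()),
                    stai_state=float(state[i]),
                    stai_trait=float(trait[i]),
                    scenarios=ScenarioResponses(float(rest[i]), float(movie[i]), float(gift[i])),
                    sas_item_scores=items[i],
                    true_params=params,
                    trials=trials,
                    **_demographics(rng),
                )
            )
            pid += 1
    return records


def _generate_addiction(config: CohortConfig, rng: np.random.Generator) -> list[ParticipantRecord]:
    n = config.n_addiction
    theta = rng.standard_normal(n)
    sas_mean, sas_sd = config.addiction_sas
    items = _sas_items_from_theta(rng, theta, sas_mean, sas_sd, config)
    totals = items.sum(axis=1)
    sas_z = (totals - totals.mean()) / totals.std(ddof=1)

    es_mean, es_sd = config.extended_self_base
    extended = _trunc_normal(rng, 0.0, es_sd, -3.5, 3.5, size=n) + es_mean + config.extended_self_slope * sas_z
    extended = np.clip(extended, 1.0, 7.0)
    fm_mean, fm_sd = config.fomo_base
    fomo = np.clip(fm_mean + config.fomo_slope * sas_z + rng.normal(0, fm_sd, n), 1.0, 5.0)
    thr_mean, thr_sd = config.social_threat_base
    threat = np.clip(thr_mean + config.social_threat_slope * sas_z + rng.normal(0, thr_sd, n), 1.0, 5.0)
    ax_b, ax_sd = config.anxiety_base
    anx = ax_b + config.anxiety_on_extended_self * extended + rng.normal(0, ax_sd, n)
    anx = np.clip(anx, *config.anxiety_range)

    median = float(np.median(totals))
    records = []
    for i in range(n):
        records.append(
            ParticipantRecord(
                id=i,
                group="low" if totals[i] <= median else "high",
                sas_total=float(totals[i]),
                stai_state=float(anx[i]),
                stai_trait=float("nan"),
                scenarios=ScenarioResponses(30.0, 50.0, 25.0),  # not measured in this design
                sas_item_scores=items[i],
                extended_self=float(extended[i]),
                fomo_mean=float(fomo[i]),
                social_threat_mean=float(threat[i]),
                **_demographics(rng),
            )
        )
    return records


def generate_titration_cohort(config: CohortConfig | None = None) -> list[ParticipantRecord]:
    """Titration cohort: latent hyperbolic k, logistic response noise.

    Each participant holds a latent discount rate k drawn lognormally; at
    each grid amount X the immediate option is chosen with probability
    logistic((X - V)/tau) where V = A/(1 + k D) is the delayed reward's
    present value and tau the response-noise temperature (0 = deterministic
    threshold).  SAS totals are generated independently of k, emulating the
    null correlation structure of the questionnaire studies.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_titration
    ks = np.exp(rng.normal(config.log_k_mean, config.log_k_sd, size=n))
    theta = rng.standard_normal(n)
    sas_mean, sas_sd = config.addiction_sas
    items = _sas_items_from_theta(rng, theta, sas_mean, sas_sd, config)
    rest = _trunc_normal(rng, 27.0, 13.0, 5, 60, size=n)
    movie = _trunc_normal(rng, 75.0, 25.0, 1, 100, size=n)
    gift = _trunc_normal(rng, 26.0, 13.0, 1, 50, size=n)

    grid = np.asarray(DEFAULT_GRID)
    records = []
    for i in range(n):
        value = hyperbolic_value(DEFAULT_DELAYED_AMOUNT, DEFAULT_DELAY_DAYS, ks[i])
        if config.titration_noise > 0:
            p_imm = 1.0 / (1.0 + np.exp(-(grid - value) / config.titration_noise))
            imm = rng.random(len(grid)) < p_imm
        else:
            imm = grid > value
        responses = tuple("immediate" if im else "delayed" for im in imm)
        series = TitrationSeries(
            immediate_amounts=tuple(grid),
            fixed_delayed_amount=DEFAULT_DELAYED_AMOUNT,
            delay_days=DEFAULT_DELAY_DAYS,
            responses=responses,
        )
        records.append(
            ParticipantRecord(
                id=i,
                group="all",
                sas_total=float(items[i].sum()),
                stai_state=float("nan"),
                stai_trait=float("nan"),
                scenarios=ScenarioResponses(float(rest[i]), float(movie[i]), float(gift[i])),
                sas_item_scores=items[i],
                titration=series,
                true_k=float(ks[i]),
                **_demographics(rng),
            )
        )
    return records


def generate_mediation_truth(
    config: CohortConfig | None = None, n: int = 72, rng_seed=None
) -> tuple[pd.DataFrame, dict]:
    """Linear-Gaussian serial chain x -> m1 -> m2 -> y with known paths.

    Returns the data and a truth dict containing each path coefficient and
    the implied indirect effects (serial: a1*d21*b2; via m1: a1*b1; via m2:
    a2*b2).  x is standard normal; every structural residual has the
    configured noise SD.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    p = config.mediation_paths
    sd = config.mediation_noise_sd
    x = rng.standard_normal(n)
    m1 = p["a1"] * x + rng.normal(0, sd, n)
    m2 = p["a2"] * x + p["d21"] * m1 + rng.normal(0, sd, n)
    y = p["c_prime"] * x + p["b1"] * m1 + p["b2"] * m2 + rng.normal(0, sd, n)
    truth = dict(p)
    truth["indirect_serial"] = p["a1"] * p["d21"] * p["b2"]
    truth["indirect_via_m1"] = p["a1"] * p["b1"]
    truth["indirect_via_m2"] = p["a2"] * p["b2"]
    return pd.DataFrame({"x": x, "m1": m1, "m2": m2, "y": y}), truth


# ---------------------------------------------------------------------------
# Tabular interfaces
# ---------------------------------------------------------------------------

PARTICIPANT_COLUMNS = [
    "participant_id", "group", "sas_total", "stai_state", "stai_trait",
    "restaurant_wait", "movie_timing", "gift_compensation", "extended_self",
    "fomo_mean", "social_threat_mean", "indifference_point", "k", "n_impulsive",
]


def participants_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Participant CSV schema; task-derived columns filled where applicable."""
    from .tasks import count_impulsive_choices, discount_rate_k, indifference_point

    rows = []
    for rec in records:
        ip = float("nan")
        k_hat = float("nan")
        if rec.titration is not None:
            ip, _ = indifference_point(rec.titration)
            if 0 < ip <= rec.titration.fixed_delayed_amount:
                k_hat = discount_rate_k(ip, rec.titration.fixed_delayed_amount, rec.titration.delay_days)
        rows.append(
            {
                "participant_id": rec.id,
                "group": rec.group,
                "sas_total": rec.sas_total,
                "stai_state": rec.stai_state,
                "stai_trait": rec.stai_trait,
                "restaurant_wait": rec.scenarios.restaurant_wait,
                "movie_timing": rec.scenarios.movie_timing,
                "gift_compensation": rec.scenarios.gift_compensation,
                "extended_self": rec.extended_self,
                "fomo_mean": rec.fomo_mean,
                "social_threat_mean": rec.social_threat_mean,
                "indifference_point": ip,
                "k": k_hat,
                "n_impulsive": count_impulsive_choices(rec.trials) if rec.trials else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS)


def truth_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Latent ground-truth table for recovery tests."""
    rows = []
    for rec in records:
        row = {"participant_id": rec.id}
        if rec.true_params is not None:
            row.update(
                {
                    "true_z": rec.true_params.z,
                    "true_a": rec.true_params.a,
                    "true_t0": rec.true_params.t0,
                    "true_dc": rec.true_params.dc,
                    "true_wm": rec.true_params.wm,
                    "true_wd": rec.true_params.wd,
                }
            )
        row["true_k"] = rec.true_k
        rows.append(row)
    return pd.DataFrame(rows)


def sas_items_matrix(records: Sequence[ParticipantRecord]) -> np.ndarray:
    return np.vstack([rec.sas_item_scores for rec in records])
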