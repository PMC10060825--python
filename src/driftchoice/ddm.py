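"""Two-boundary drift diffusion machinery for intertemporal choice.

The decision between a smaller-sooner (SS) and a larger-later (LL) monetary
option is modelled as noisy evidence accumulation between two absorbing
boundaries: evidence ``x`` starts at ``z * a`` (a fraction ``z`` of the
boundary separation ``a``), drifts at rate ``v`` and diffuses with noise
scale ``s`` until it hits ``a`` (choose LL) or ``0`` (choose SS).  The drift
rate is a linear function of the attribute differences between the options::

    v = dc + wm * money_diff + wd * delay_diff

so ``wm`` is the decision weight placed on the extra money the delayed
option offers (per currency unit) and ``wd`` the weight on the extra delay
(per day, typically negative).  Observed reaction time is the boundary
crossing time plus a non-decision component ``t0``.

This module provides the deterministic pieces (drift rate, analytic
absorption probability, Wiener first-passage-time density, likelihood) and
an Euler–Maruyama trial simulator that the analytic expressions are checked
against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChoicePair",
    "DDMParams",
    "TrialRecord",
    "drift_rate",
    "choice_probability",
    "wfpt_density",
    "wfpt_logpdf",
    "simulate_trial",
    "simulate_trials",
    "simulate_first_passage",
    "negative_log_likelihood",
    "trials_to_frame",
    "read_trials_csv",
    "write_trials_csv",
]

# Numerical policy for the whole module: series truncation accuracy for the
# first-passage density, density floor for out-of-support reaction times in
# the likelihood, and simulator defaults.
SERIES_TOL = 1e-10
DENSITY_FLOOR = 1e-12
DEFAULT_DT = 0.001
MAX_DECISION_TIME = 20.0

CHOICE_LL = "LL"  # upper boundary: larger-later / delayed option
CHOICE_SS = "SS"  # lower boundary: smaller-sooner / immediate option


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChoicePair:
    """One intertemporal option pair.

    Amounts are in task currency units, delays in days.  The delayed option
    must strictly dominate on amount and be strictly later, so the derived
    attribute differences are positive.
    """

    amount_ss: float
    delay_ss: float
    amount_ll: float
    delay_ll: float

    def __post_init__(self) -> None:
        if not (self.amount_ll > self.amount_ss > 0):
            raise ValueError(
                f"need amount_ll > amount_ss > 0, got {self.amount_ll}, {self.amount_ss}"
            )
        if not (self.delay_ll > self.delay_ss >= 0):
            raise ValueError(
                f"need delay_ll > delay_ss >= 0, got {self.delay_ll}, {self.delay_ss}"
            )

    @property
    def money_diff(self) -> float:
        return self.amount_ll - self.amount_ss

    @property
    def delay_diff(self) -> float:
        return self.delay_ll - self.delay_ss


@dataclass(frozen=True)
class DDMParams:
    """The six fitted diffusion parameters plus the fixed noise scale.

    ``s`` is not identifiable jointly with (a, dc, wm, wd) and is held at 1
    by convention; estimates on another noise convention are a deterministic
    rescaling (v, a, s) -> (c v, c a, c s).
    """

    z: float = 0.5
    a: float = 1.5
    t0: float = 0.3
    dc: float = 0.0
    wm: float = 0.0
    wd: float = 0.0
    s: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.z < 1.0):
            raise ValueError(f"relative starting point z must be in (0,1), got {self.z}")
        if self.a <= 0:
            raise ValueError(f"threshold a must be > 0, got {self.a}")
        if self.t0 < 0:
            raise ValueError(f"non-decision time t0 must be >= 0, got {self.t0}")
        if self.s <= 0:
            raise ValueError(f"noise scale s must be > 0, got {self.s}")

    def as_array(self) -> np.ndarray:
        return np.array([self.z, self.a, self.t0, self.dc, self.wm, self.wd])


@dataclass(frozen=True)
class TrialRecord:
    """A single recorded choice (LL = delayed, SS = immediate) with its RT."""

    pair: ChoicePair
    choice: str
    rt: float
    censored: bool = False

    def __post_init__(self) -> None:
        if self.choice not in (CHOICE_LL, CHOICE_SS):
            raise ValueError(f"choice must be '{CHOICE_LL}' or '{CHOICE_SS}', got {self.choice!r}")
        if self.rt <= 0:
            raise ValueError(f"rt must be > 0, got {self.rt}")


# ---------------------------------------------------------------------------
# Drift and analytic absorption probability
# ---------------------------------------------------------------------------

def drift_rate(params: DDMParams, pair: ChoicePair) -> float:
    """Attribute-weighted drift: dc + wm*money_diff + wd*delay_diff."""
    return params.dc + params.wm * pair.money_diff + params.wd * pair.delay_diff


def drift_rates(params: DDMParams, money_diff: np.ndarray, delay_diff: np.ndarray) -> np.ndarray:
    return params.dc + params.wm * np.asarray(money_diff) + params.wd * np.asarray(delay_diff)


def choice_probability(v, a, z, s: float = 1.0):
    """Probability of absorption at the upper (LL) boundary.

    For drift v, boundary separation a, relative start z and noise s this is
    (1 - exp(-2 v z a / s^2)) / (1 - exp(-2 v a / s^2)); the v -> 0 limit is
    z.  Evaluated stably for large |v| a / s^2.  Accepts scalars or arrays.
    """
    v = np.asarray(v, dtype=float)
    a = np.asarray(a, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(a <= 0) or np.any(z <= 0) or np.any(z >= 1) or s <= 0:
        raise ValueError("require a > 0, 0 < z < 1, s > 0")
    b = 2.0 * v * a / (s * s)
    out = np.empty(np.broadcast(v, a, z).shape, dtype=float)
    b, z_b = np.broadcast_arrays(b, z)
    small = np.abs(b) < 1e-9
    big_pos = b > 500.0
    big_neg = b < -500.0
    mid = ~(small | big_pos | big_neg)
    out[small] = z_b[small]
    out[big_pos] = -np.expm1(-b[big_pos] * z_b[big_pos])  # ~ 1
    # For strongly negative b both expm1 terms blow up; work on the log scale:
    # P ~ exp(b (1 - z)).
    out[big_neg] = np.exp(b[big_neg] * (1.0 - z_b[big_neg]))
    out[mid] = np.expm1(-b[mid] * z_b[mid]) / np.expm1(-b[mid])
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Wiener first-passage-time density (dual series expansion)
# ---------------------------------------------------------------------------

def _fpt_std_small(tt: np.ndarray, w: np.ndarray, n_terms: int) -> np.ndarray:
    """Small-time series of the standardized (v=0, a=1) lower-boundary density."""
    ks = np.arange(-math.floor((n_terms - 1) / 2), math.ceil((n_terms - 1) / 2) + 1)
    arg = w[None, :] + 2.0 * ks[:, None]
    dens = np.sum(arg * np.exp(-(arg * arg) / (2.0 * tt[None, :])), axis=0)
    return dens / np.sqrt(2.0 * math.pi * tt**3)


def _fpt_std_large(tt: np.ndarray, w: np.ndarray, n_terms: int) -> np.ndarray:
    """Large-time (eigenfunction) series of the standardized density."""
    ks = np.arange(1, n_terms + 1, dtype=float)
    dens = np.sum(
        ks[:, None]
        * np.exp(-(ks[:, None] ** 2) * math.pi**2 * tt[None, :] / 2.0)
        * np.sin(ks[:, None] * math.pi * w[None, :]),
        axis=0,
    )
    return math.pi * dens


def _wfpt_lower_logpdf(t: np.ndarray, v: np.ndarray, a: np.ndarray, w: np.ndarray,
                       s: float = 1.0) -> np.ndarray:
    """Log density of first passage through the LOWER boundary at time t.

    Standard dual-expansion evaluation: rescale to a unit-noise, unit-boundary
    process, pick the series (small- vs large-time) that needs fewer terms for
    truncation error below SERIES_TOL, and add the drift factor back in log
    space.  Fully vectorized over trials; non-positive t gets -inf.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    v = np.broadcast_to(np.asarray(v, dtype=float) / s, t.shape).copy()
    a_u = np.broadcast_to(np.asarray(a, dtype=float) / s, t.shape)
    w = np.broadcast_to(np.asarray(w, dtype=float), t.shape)

    out = np.full(t.shape, -np.inf)
    ok = t > 0
    if not np.any(ok):
        return out
    t_ok, v_ok, a_ok, w_ok = t[ok], v[ok], a_u[ok], w[ok]
    tt = t_ok / (a_ok * a_ok)  # normalized time

    err = SERIES_TOL
    # term counts per Navarro & Fuss (2009)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond_s = 2.0 * np.sqrt(2.0 * math.pi * tt) * err < 1.0
        ks = np.where(
            cond_s,
            2.0 + np.sqrt(np.maximum(-2.0 * tt * np.log(2.0 * err * np.sqrt(2.0 * math.pi * tt)), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(tt) + 1.0)
        cond_l = math.pi * tt * err < 1.0
        kl = np.where(
            cond_l,
            np.sqrt(np.maximum(-2.0 * np.log(math.pi * tt * err), 0.0) / (math.pi**2 * tt)),
            1.0 / (math.pi * np.sqrt(tt)),
        )
        kl = np.maximum(kl, 1.0 / (math.pi * np.sqrt(tt)))

    use_small = ks < kl
    dens_std = np.empty_like(tt)
    if np.any(use_small):
        n_terms = int(min(np.ceil(ks[use_small].max()), 64))
        dens_std[use_small] = _fpt_std_small(tt[use_small], w_ok[use_small], n_terms)
    if np.any(~use_small):
        n_terms = int(min(np.ceil(kl[~use_small].max()), 64))
        dens_std[~use_small] = _fpt_std_large(tt[~use_small], w_ok[~use_small], n_terms)
    dens_std = np.maximum(dens_std, 0.0)

    with np.errstate(divide="ignore"):
        logpdf = (
            np.log(dens_std)
            - 2.0 * np.log(a_ok)
            - v_ok * a_ok * w_ok
            - (v_ok * v_ok) * t_ok / 2.0
        )
    out[ok] = logpdf
    return out


def wfpt_logpdf(t, v, a, z, s: float = 1.0, boundary: str = "upper") -> np.ndarray:
    """Log first-passage density at the requested boundary (vectorized).

    Upper-boundary passage of a process with drift v starting at fraction z
    equals lower-boundary passage of the mirrored process (drift -v, start
    1 - z).
    """
    if boundary == "upper":
        return _wfpt_lower_logpdf(t, -np.asarray(v, dtype=float), a, 1.0 - np.asarray(z, dtype=float), s)
    if boundary == "lower":
        return _wfpt_lower_logpdf(t, v, a, z, s)
    raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")


def wfpt_density(t, v, a, z, s: float = 1.0, boundary: str = "upper"):
    """First-passage-time density of the diffusion at one boundary.

    ``t`` is decision time (RT minus non-decision time), strictly positive.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("decision time t must be > 0")
    out = np.exp(wfpt_logpdf(t_arr, v, a, z, s, boundary))
    return float(out[0]) if np.ndim(t) == 0 else out


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_first_passage(
    v,
    a: float,
    z: float,
    s: float = 1.0,
    n: int | None = None,
    rng: np.random.Generator | int | None = None,
    dt: float = DEFAULT_DT,
    max_time: float = MAX_DECISION_TIME,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Euler–Maruyama first-passage simulation.

    Steps x_{t+dt} = x_t + v dt + s sqrt(dt) N(0,1) from x_0 = z*a until the
    path leaves [0, a].  Because the path is only monitored at the step
    times, excursions that cross a boundary and return within one step are
    missed; the Broadie–Glasserman continuity correction compensates by
    registering crossings against boundaries inset by 0.5826 * s * sqrt(dt),
    which removes the O(sqrt(dt)) bias in both absorption probabilities and
    passage times.  Returns (upper_hit bool, decision_time, censored bool);
    censored paths (no absorption before ``max_time``) report the cap and
    the boundary nearer to the final position.  ``v`` may be a scalar (with
    ``n`` replicates) or one drift per simulated trial.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = np.random.default_rng(rng)
    v = np.asarray(v, dtype=float)
    if v.ndim == 0:
        if n is None:
            n = 1
        v = np.full(n, float(v))
    n = v.size

    x = np.full(n, z * a)
    upper = np.zeros(n, dtype=bool)
    times = np.full(n, max_time)
    censored = np.ones(n, dtype=bool)
    alive = np.arange(n)
    sqdt = s * math.sqrt(dt)
    # continuity-corrected monitoring boundaries (Broadie-Glasserman beta1)
    inset = 0.5826 * s * math.sqrt(dt)
    hi = max(a - inset, a * 0.5)
    lo = min(inset, a * 0.5)
    block = 128
    n_steps = int(math.ceil(max_time / dt))
    step = 0
    while alive.size and step < n_steps:
        nb = min(block, n_steps - step)
        incr = v[alive, None] * dt + sqdt * rng.standard_normal((alive.size, nb))
        paths = x[alive, None] + np.cumsum(incr, axis=1)
        hit = (paths >= hi) | (paths <= lo)
        any_hit = hit.any(axis=1)
        first = np.argmax(hit, axis=1)
        done = alive[any_hit]
        idx = first[any_hit]
        times[done] = (step + idx + 1) * dt
        upper[done] = paths[any_hit, idx] >= hi
        censored[done] = False
        x[alive] = paths[:, -1]
        alive = alive[~any_hit]
        step += nb
    if np.any(censored):
        upper[censored] = x[censored] >= a / 2.0
    return upper, times, censored


def simulate_trials(
    params: DDMParams,
    pairs: Sequence[ChoicePair],
    rng: np.random.Generator | int | None = None,
    dt: float = DEFAULT_DT,
    max_decision_time: float = MAX_DECISION_TIME,
) -> list[TrialRecord]:
    """Simulate one trial per choice pair under ``params`` (vectorized)."""
    md = np.array([p.money_diff for p in pairs])
    dd = np.array([p.delay_diff for p in pairs])
    v = drift_rates(params, md, dd)
    upper, t_dec, censored = simulate_first_passage(
        v, params.a, params.z, params.s, rng=rng, dt=dt, max_time=max_decision_time
    )
    return [
        TrialRecord(
            pair=pair,
            choice=CHOICE_LL if up else CHOICE_SS,
            rt=float(td + params.t0),
            censored=bool(c),
        )
        for pair, up, td, c in zip(pairs, upper, t_dec, censored)
    ]


def simulate_trial(
    params: DDMParams,
    pair: ChoicePair,
    dt: float = DEFAULT_DT,
    rng_seed: np.random.Generator | int | None = None,
) -> TrialRecord:
    """Simulate a single trial; rt = first-passage time + t0."""
    return simulate_trials(params, [pair], rng=rng_seed, dt=dt)[0]


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _trial_arrays(trials: Sequence[TrialRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    md = np.array([t.pair.money_diff for t in trials])
    dd = np.array([t.pair.delay_diff for t in trials])
    rt = np.array([t.rt for t in trials])
    is_ll = np.array([t.choice == CHOICE_LL for t in trials])
    return md, dd, rt, is_ll


def negative_log_likelihood(params: DDMParams, trials: Sequence[TrialRecord]) -> float:
    """Summed negative log Wiener first-passage density over trials.

    Each trial contributes the density of its decision time (rt - t0) at the
    boundary matching its recorded choice; trials whose rt does not exceed t0
    contribute a floored density of 1e-12 so the objective stays finite.
    """
    if len(trials) == 0:
        raise ValueError("negative_log_likelihood requires at least one trial")
    md, dd, rt, is_ll = _trial_arrays(trials)
    return _nll_from_arrays(params.as_array(), md, dd, rt, is_ll, params.s)


def _nll_from_arrays(theta: np.ndarray, md: np.ndarray, dd: np.ndarray,
                     rt: np.ndarray, is_ll: np.ndarray, s: float = 1.0) -> float:
    """Vectorized objective used by both the public API and the optimizer."""
    z, a, t0, dc, wm, wd = theta
    v = dc + wm * md + wd * dd
    t = rt - t0
    logp = np.full(rt.shape, math.log(DENSITY_FLOOR))
    ok = t > 0
    if np.any(ok & is_ll):
        sel = ok & is_ll
        logp[sel] = _wfpt_lower_logpdf(t[sel], -v[sel], a, 1.0 - z, s)
    if np.any(ok & ~is_ll):
        sel = ok & ~is_ll
        logp[sel] = _wfpt_lower_logpdf(t[sel], v[sel], a, z, s)
    logp = np.maximum(logp, math.log(DENSITY_FLOOR))
    return float(-np.sum(logp))


# ---------------------------------------------------------------------------
# Trial CSV interface
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = [
    "participant_id",
    "amount_ss",
    "delay_ss",
    "amount_ll",
    "delay_ll",
    "choice",
    "rt_seconds",
]


def trials_to_frame(trials: Sequence[TrialRecord], participant_id: str | int = 0) -> pd.DataFrame:
    """One row per trial; choice coded 0 = SS (immediate), 1 = LL (delayed)."""
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "amount_ss": [t.pair.amount_ss for t in trials],
            "delay_ss": [t.pair.delay_ss for t in trials],
            "amount_ll": [t.pair.amount_ll for t in trials],
            "delay_ll": [t.pair.delay_ll for t in trials],
            "choice": [1 if t.choice == CHOICE_LL else 0 for t in trials],
            "rt_seconds": [t.rt for t in trials],
        },
        columns=TRIAL_COLUMNS,
    )


def frame_to_trials(frame: pd.DataFrame) -> list[TrialRecord]:
    return [
        TrialRecord(
            pair=ChoicePair(row.amount_ss, row.delay_ss, row.amount_ll, row.delay_ll),
            choice=CHOICE_LL if int(row.choice) == 1 else CHOICE_SS,
            rt=float(row.rt_seconds),
        )
        for row in frame.itertuples()
    ]


def write_trials_csv(path, trials_by_participant: dict) -> None:
    frames = [trials_to_frame(trials, pid) for pid, trials in trials_by_participant.items()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trials_csv(path) -> dict:
    frame = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    return {pid: frame_to_trials(g) for pid, g in frame.groupby("participant_id", sort=False)}
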