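"""Scoring of the non-diffusion behavioral instruments.

Covers the titration delay-discounting task (indifference point and
hyperbolic discount rate k), impulsive-choice counting on binary trials,
and the three impulsive-purchase scenarios (restaurant wait, movie timing,
gift compensation) with their reverse-coding and cohort standardization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ddm import CHOICE_SS, TrialRecord

__all__ = [
    "TitrationSeries",
    "ScenarioResponses",
    "indifference_point",
    "discount_rate_k",
    "count_impulsive_choices",
    "impulsive_purchase_scores",
    "hyperbolic_value",
]

# Scenario scale bounds (minutes, 1-100 scale, currency) and the reverse-coding
# constant for the 5-60 minute restaurant scale: reversed = 65 - wait.
RESTAURANT_RANGE = (5.0, 60.0)
MOVIE_RANGE = (1.0, 100.0)
GIFT_RANGE = (1.0, 50.0)
RESTAURANT_REVERSE_CONST = 65.0
MOVIE_REVERSE_CONST = 101.0

DEFAULT_GRID = tuple(float(x) for x in range(10, 201, 10))
DEFAULT_DELAYED_AMOUNT = 200.0
DEFAULT_DELAY_DAYS = 60.0  # "2 months"


@dataclass(frozen=True)
class TitrationSeries:
    """One participant's titration responses.

    ``immediate_amounts`` is the strictly ascending grid of immediate offers
    X tested against the fixed delayed reward; ``responses`` records, per X,
    whether the immediate ('immediate') or delayed ('delayed') option was
    chosen.
    """

    immediate_amounts: tuple = DEFAULT_GRID
    fixed_delayed_amount: float = DEFAULT_DELAYED_AMOUNT
    delay_days: float = DEFAULT_DELAY_DAYS
    responses: tuple = ()

    def __post_init__(self) -> None:
        grid = np.asarray(self.immediate_amounts, dtype=float)
        if len(grid) == 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("immediate_amounts must be a strictly ascending grid")
        if len(self.responses) != len(grid):
            raise ValueError("responses must match the grid length")
        bad = set(self.responses) - {"immediate", "delayed"}
        if bad:
            raise ValueError(f"responses must be 'immediate'/'delayed', got {bad}")


@dataclass(frozen=True)
class ScenarioResponses:
    restaurant_wait: float  # minutes willing to wait, 5-60
    movie_timing: float  # 1 = before the deadline ... 100 = after the deadline
    gift_compensation: float  # expected compensation value, 1-50

    def __post_init__(self) -> None:
        for value, (lo, hi), name in (
            (self.restaurant_wait, RESTAURANT_RANGE, "restaurant_wait"),
            (self.movie_timing, MOVIE_RANGE, "movie_timing"),
            (self.gift_compensation, GIFT_RANGE, "gift_compensation"),
        ):
            if not (lo <= value <= hi):
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")


def indifference_point(series: TitrationSeries) -> tuple[float, bool]:
    """Indifference point of a titration series under the monotone-switch rule.

    Participants are expected to prefer the delayed reward at small immediate
    offers and switch to the immediate reward once X exceeds the delayed
    reward's present value; the indifference point is the midpoint of the
    grid values bracketing the first delayed->immediate switch.  All-delayed
    series are censored high (grid max + half step), all-immediate censored
    low (grid min - half step, floored at 0).  Non-monotone series (multiple
    switches) use the first switch and are flagged in the returned boolean.
    """
    if len(series.responses) == 0:
        raise ValueError("empty titration responses")
    grid = np.asarray(series.immediate_amounts, dtype=float)
    immediate = np.array([r == "immediate" for r in series.responses])
    step = grid[1] - grid[0] if len(grid) > 1 else grid[0]
    switches = int(np.sum(np.abs(np.diff(immediate.astype(int)))))
    multi_switch = switches > 1

    if not immediate.any():  # always waited for the delayed reward
        return float(grid[-1] + step / 2.0), multi_switch
    first = int(np.argmax(immediate))
    if first == 0:  # immediate preferred everywhere
        return float(max(grid[0] - step / 2.0, 0.0)), multi_switch
    return float((grid[first - 1] + grid[first]) / 2.0), multi_switch


def hyperbolic_value(amount: float, delay_days: float, k: float) -> float:
    """Present value under hyperbolic discounting: V = A / (1 + k*D)."""
    return amount / (1.0 + k * delay_days)


def discount_rate_k(
    indifference: float,
    delayed_amount: float,
    delay_days: float,
    form: str = "hyperbolic",
) -> float:
    """Discount rate implied by an indifference point.

    Hyperbolic (default): the indifference amount V satisfies
    V = A / (1 + k*D), so k = (A/V - 1)/D.  The exponential alternative
    (V = A * exp(-k*D)) gives k = ln(A/V)/D.  k is per day and >= 0, with
    k = 0 exactly when the delayed reward is not discounted at all.
    """
    if indifference <= 0:
        raise ValueError("indifference point must be > 0")
    if not (indifference <= delayed_amount):
        raise ValueError("indifference point cannot exceed the delayed amount")
    if delay_days <= 0:
        raise ValueError("delay must be > 0")
    if form == "hyperbolic":
        return (delayed_amount / indifference - 1.0) / delay_days
    if form == "exponential":
        return float(np.log(delayed_amount / indifference) / delay_days)
    raise ValueError(f"form must be 'hyperbolic' or 'exponential', got {form!r}")


def count_impulsive_choices(trials: Sequence[TrialRecord]) -> int:
    """Number of trials where the smaller-sooner (immediate) reward was taken."""
    return sum(1 for t in trials if t.choice == CHOICE_SS)


def impulsive_purchase_scores(responses: Sequence[ScenarioResponses]) -> pd.DataFrame:
    """Standardized per-scenario impulsivity scores for a cohort.

    Higher = more impulsive in every column: restaurant wait is reverse-coded
    (65 - minutes) and movie timing reverse-coded (101 - scale value, since
    high raw values mean waiting until after the deadline); gift compensation
    enters as-is.  Scores are z-standardized against the supplied cohort with
    the sample SD (n-1).
    """
    if len(responses) < 2:
        raise ValueError("need at least 2 respondents to standardize")
    raw = pd.DataFrame(
        {
            "restaurant": [RESTAURANT_REVERSE_CONST - r.restaurant_wait for r in responses],
            "movie": [MOVIE_REVERSE_CONST - r.movie_timing for r in responses],
            "gift": [r.gift_compensation for r in responses],
        }
    )
    sds = raw.std(ddof=1)
    if (sds == 0).any():
        flat = list(sds.index[sds == 0])
        raise ValueError(f"cohort SD is zero for scenario(s) {flat}; cannot standardize")
    return (raw - raw.mean()) / sds
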