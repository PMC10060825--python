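"""Inferential layer: ANOVA/ANCOVA, correlations, reliability, mediation.

Group contrasts are two-group one-way ANOVAs (F = squared pooled t) with eta
squared as the effect size; covariate-adjusted contrasts go through an OLS
fit.  Mediation follows the PROCESS conventions: OLS path models, indirect
effects as products of path coefficients, and percentile confidence
intervals from case-resampled bootstrap replicates (default 5,000).  All
p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "GroupStats",
    "AnovaResult",
    "MediationResult",
    "oneway_f_from_groups",
    "oneway_f_from_values",
    "eta_squared",
    "ancova_group_effect",
    "pearson_r",
    "cronbach_alpha",
    "median_split",
    "zscore",
    "mediation_simple",
    "mediation_serial",
    "mediation_parallel",
]


@dataclass(frozen=True)
class GroupStats:
    """Sample mean, SD (n-1 denominator) and size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @classmethod
    def from_values(cls, x) -> "GroupStats":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=len(x))


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df1: int
    df2: int
    p: float
    eta_sq: float


@dataclass(frozen=True)
class MediationResult:
    paths: dict
    indirect: float
    boot_se: float
    ci_low: float
    ci_high: float
    n_boot: int
    other_indirects: dict = field(default_factory=dict)
    other_cis: dict = field(default_factory=dict)


def eta_squared(f: float, df1: int, df2: int) -> float:
    """Proportion of variance explained: F*df1 / (F*df1 + df2)."""
    if f < 0 or df1 < 1 or df2 < 1:
        raise ValueError("require f >= 0 and dfs >= 1")
    return f * df1 / (f * df1 + df2)


def oneway_f_from_groups(g1: GroupStats, g2: GroupStats) -> AnovaResult:
    """Two-group one-way ANOVA from summary statistics (F = pooled t squared)."""
    df2 = g1.n + g2.n - 2
    pooled_var = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df2
    diff = g1.mean - g2.mean
    if pooled_var == 0:
        if diff == 0:
            return AnovaResult(0.0, 1, df2, 1.0, 0.0)
        return AnovaResult(float("inf"), 1, df2, 0.0, 1.0)
    f = diff**2 / (pooled_var * (1.0 / g1.n + 1.0 / g2.n))
    p = float(scipy.stats.f.sf(f, 1, df2))
    return AnovaResult(float(f), 1, df2, p, eta_squared(f, 1, df2))


def oneway_f_from_values(x1, x2) -> AnovaResult:
    return oneway_f_from_groups(GroupStats.from_values(x1), GroupStats.from_values(x2))


def ancova_group_effect(y, group, covariates=None) -> AnovaResult:
    """F for the (binary) group term in a covariate-adjusted linear model.

    ``covariates`` is an optional DataFrame; numeric columns enter as-is and
    object/categorical columns are dummy-coded (first level dropped).  With
    no covariates this reduces exactly to the one-way ANOVA.  A single-df
    group term makes the Type III F equal to the squared coefficient t.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError(f"group must be binary, found levels {levels}")
    g = (group == levels[1]).astype(float)

    design = pd.DataFrame({"const": np.ones(len(y)), "group": g})
    if covariates is not None and len(getattr(covariates, "columns", [])) > 0:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        cov = pd.get_dummies(cov, drop_first=True, dtype=float)
        for col in cov.columns:
            design[str(col)] = cov[col].to_numpy(dtype=float)

    X = design.to_numpy()
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 2")
    # locate a collinear column by incremental rank checks
    rank = 0
    for j, col in enumerate(design.columns):
        new_rank = np.linalg.matrix_rank(X[:, : j + 1])
        if new_rank == rank:
            raise ValueError(f"covariate matrix is rank deficient: column '{col}' is collinear")
        rank = new_rank

    model = sm.OLS(y, X).fit()
    t = model.tvalues[1]
    f = float(t**2)
    df2 = int(model.df_resid)
    return AnovaResult(f, 1, df2, float(scipy.stats.f.sf(f, 1, df2)), eta_squared(f, 1, df2))


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def cronbach_alpha(items) -> float:
    """Internal-consistency reliability of a respondent-by-item score matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of total score),
    with sample (n-1) variances.  Can be negative for incoherent scales.
    """
    items = np.asarray(items, dtype=float)
    if items.ndim != 2 or items.shape[0] < 2 or items.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 respondents and >= 2 items")
    k = items.shape[1]
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero")
    item_var = items.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def median_split(scores) -> tuple[np.ndarray, float]:
    """Labels 'low' (score <= median, ties included) / 'high', plus the median."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 2:
        raise ValueError("median_split needs n >= 2")
    med = float(np.median(scores))
    labels = np.where(scores <= med, "low", "high")
    if (labels == "low").all() or (labels == "high").all():
        import warnings

        warnings.warn("median split produced an empty group (all scores equal)", stacklevel=2)
    return labels, med


def zscore(x) -> np.ndarray:
    """Standardize with the sample SD (n-1), matching PROCESS preprocessing."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def _ols_coef(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def _batch_ols(cols: list, y: np.ndarray) -> np.ndarray:
    """OLS coefficients for a batch of resampled datasets.

    ``cols`` are predictor arrays of shape (B, n) (an intercept column is
    prepended); ``y`` is (B, n).  Solved through the normal equations in one
    batched call; the rare singular resample falls back to lstsq.
    """
    B, n = y.shape
    X = np.stack([np.ones((B, n))] + list(cols), axis=2)
    XtX = np.einsum("bnp,bnq->bpq", X, X)
    Xty = np.einsum("bnp,bn->bp", X, y)
    try:
        return np.linalg.solve(XtX, Xty[..., None])[..., 0]
    except np.linalg.LinAlgError:
        return np.array([np.linalg.lstsq(X[i], y[i], rcond=None)[0] for i in range(B)])


def _check_mediation_inputs(*vectors) -> int:
    n = len(vectors[0])
    for v in vectors:
        if len(v) != n:
            raise ValueError("all mediation vectors must have equal length")
    if n < 10:
        raise ValueError("mediation requires n >= 10")
    cols = np.column_stack(vectors)
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), cols])) < cols.shape[1] + 1:
        raise ValueError("mediation design is collinear")
    return n


def _boot_ci(stats: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    lo, hi = np.percentile(stats, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(stats.std(ddof=1)), float(lo), float(hi)


def mediation_simple(x, m, y, n_boot: int = 5000, rng_seed=0) -> MediationResult:
    """Single-mediator model (PROCESS Model 4): indirect = a*b.

    Paths: a from m ~ x, b and c' from y ~ x + m, all OLS with intercepts;
    the CI is the percentile interval of a*b over case-resampled replicates.
    Standardize inputs upstream if standardized coefficients are wanted.
    """
    x, m, y = (np.asarray(v, dtype=float) for v in (x, m, y))
    n = _check_mediation_inputs(x, m, y)
    rng = np.random.default_rng(rng_seed)

    def paths(xi, mi, yi):
        one = np.ones(len(xi))
        a = _ols_coef(mi, np.column_stack([one, xi]))[1]
        cb = _ols_coef(yi, np.column_stack([one, xi, mi]))
        return a, cb[2], cb[1]  # a, b, c'

    a, b, c_prime = paths(x, m, y)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, mb, yb = x[idx], m[idx], y[idx]
    a_b = _batch_ols([xb], mb)[:, 1]
    b_b = _batch_ols([xb, mb], yb)[:, 2]
    se, lo, hi = _boot_ci(a_b * b_b)
    return MediationResult(
        paths={"a": float(a), "b": float(b), "c_prime": float(c_prime)},
        indirect=float(a * b),
        boot_se=se,
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
    )


def mediation_serial(x, m1, m2, y, n_boot: int = 5000, rng_seed=0) -> MediationResult:
    """Two serial mediators (PROCESS Model 6).

    Path models: m1 ~ x (a1); m2 ~ x + m1 (a2, d21); y ~ x + m1 + m2
    (c', b1, b2).  The primary indirect effect is the serial chain
    a1*d21*b2; the two single-mediator routes (a1*b1, a2*b2) are reported
    alongside with their own percentile CIs.
    """
    x, m1, m2, y = (np.asarray(v, dtype=float) for v in (x, m1, m2, y))
    n = _check_mediation_inputs(x, m1, m2, y)
    rng = np.random.default_rng(rng_seed)

    def paths(xi, m1i, m2i, yi):
        one = np.ones(len(xi))
        a1 = _ols_coef(m1i, np.column_stack([one, xi]))[1]
        m2c = _ols_coef(m2i, np.column_stack([one, xi, m1i]))
        yc = _ols_coef(yi, np.column_stack([one, xi, m1i, m2i]))
        # a2 = x->m2, d21 = m1->m2, c' = x->y, b1 = m1->y, b2 = m2->y
        return a1, m2c[1], m2c[2], yc[1], yc[2], yc[3]

    a1, a2, d21, c_prime, b1, b2 = paths(x, m1, m2, y)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, m1b, m2b, yb = x[idx], m1[idx], m2[idx], y[idx]
    a1_b = _batch_ols([xb], m1b)[:, 1]
    m2_b = _batch_ols([xb, m1b], m2b)
    y_b = _batch_ols([xb, m1b, m2b], yb)
    a2_b, d21_b = m2_b[:, 1], m2_b[:, 2]
    b1_b, b2_b = y_b[:, 2], y_b[:, 3]
    se, lo, hi = _boot_ci(a1_b * d21_b * b2_b)
    _, lo1, hi1 = _boot_ci(a1_b * b1_b)
    _, lo2, hi2 = _boot_ci(a2_b * b2_b)
    return MediationResult(
        paths={
            "a1": float(a1),
            "a2": float(a2),
            "d21": float(d21),
            "b1": float(b1),
            "b2": float(b2),
            "c_prime": float(c_prime),
        },
        indirect=float(a1 * d21 * b2),
        boot_se=se,
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
        other_indirects={"via_m1": float(a1 * b1), "via_m2": float(a2 * b2)},
        other_cis={"via_m1": (lo1, hi1), "via_m2": (lo2, hi2)},
    )


def mediation_parallel(x, mediators, y, n_boot: int = 5000, rng_seed=0) -> dict:
    """Parallel multiple mediators (PROCESS Model 4 with k mediators).

    Each mediator is regressed on x alone; y is regressed on x plus all
    mediators jointly.  Returns one MediationResult per mediator name.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    med = {k: np.asarray(v, dtype=float) for k, v in mediators.items()}
    n = _check_mediation_inputs(x, *med.values(), y)
    rng = np.random.default_rng(rng_seed)
    names = list(med)
    M = np.column_stack([med[k] for k in names])

    def paths(xi, Mi, yi):
        one = np.ones(len(xi))
        a = np.array([_ols_coef(Mi[:, j], np.column_stack([one, xi]))[1] for j in range(Mi.shape[1])])
        coefs = _ols_coef(yi, np.column_stack([one, xi, Mi]))
        return a, coefs[2:], coefs[1]  # a_j, b_j, c'

    a, b, c_prime = paths(x, M, y)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb = x[idx]
    Mb = M[idx]  # B, n, k
    a_boots = np.stack(
        [_batch_ols([xb], Mb[:, :, j])[:, 1] for j in range(len(names))], axis=1
    )
    b_boots = _batch_ols([xb] + [Mb[:, :, j] for j in range(len(names))], y[idx])[:, 2:]
    boots = a_boots * b_boots
    out = {}
    for j, name in enumerate(names):
        se, lo, hi = _boot_ci(boots[:, j])
        out[name] = MediationResult(
            paths={"a": float(a[j]), "b": float(b[j]), "c_prime": float(c_prime)},
            indirect=float(a[j] * b[j]),
            boot_se=se,
            ci_low=lo,
            ci_high=hi,
            n_boot=n_boot,
        )
    return out
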