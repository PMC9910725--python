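"""Correlation/regression between taxonomic and functional deltas with
Monte Carlo permutation significance.

The observed Pearson r (or OLS slope of functional on taxonomic deltas) is
compared against the distribution obtained by randomly reassigning the
taxonomic values a fixed number of times while holding the functional values
in place.  Two-sided p uses the add-one correction
p = (#{|stat_perm| >= |stat_obs|} + 1) / (n_perm + 1), so p is never exactly
zero and always at least 1/(n_perm + 1).  Slopes are additionally testable
against 1 (equal taxonomic and functional response) and against each other
across scenarios, both with Student's t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of y (functional delta) on x (taxonomic delta)."""

    slope: float
    intercept: float
    r: float
    n: int
    se_slope: float

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must not exceed 1")


@dataclass(frozen=True)
class PermTestResult:
    observed: float
    statistic: str  # "r" | "slope"
    n_perm: int
    p_two_sided: float
    seed: int


@dataclass(frozen=True)
class SlopeTestResult:
    t: float
    df: int
    p: float


def fit_regression(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """Ordinary least squares of y on x with Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(np.clip(res.rvalue, -1.0, 1.0)),
        n=x.size,
        se_slope=float(res.stderr),
    )


def _stat_many(xs: np.ndarray, y: np.ndarray, statistic: str) -> np.ndarray:
    """Pearson r or OLS slope of y on each row of xs, vectorised."""
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sxy = xc @ yc
    sxx = (xc ** 2).sum(axis=1)
    if statistic == "slope":
        return sxy / sxx
    syy = float((yc ** 2).sum())
    return sxy / np.sqrt(sxx * syy)


def permutation_test(x: np.ndarray, y: np.ndarray, statistic: str = "r",
                     n_perm: int = 1000, seed: int = 0) -> PermTestResult:
    """Monte Carlo permutation test of r or slope.

    Permutes the taxonomic vector x ``n_perm`` times (y fixed), recomputes
    the statistic, and reports the two-sided add-one p.  Reproducible for a
    given seed.
    """
    if statistic not in {"r", "slope"}:
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    fit = fit_regression(x, y)
    observed = fit.r if statistic == "r" else fit.slope
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    perms = np.array([rng.permutation(x) for _ in range(n_perm)])
    null = _stat_many(perms, y, statistic)
    p = (int((np.abs(null) >= abs(observed)).sum()) + 1) / (n_perm + 1)
    return PermTestResult(
        observed=float(observed),
        statistic=statistic,
        n_perm=n_perm,
        p_two_sided=float(p),
        seed=seed,
    )


def slope_vs_one(fit: RegressionFit, se_slope: float | None = None) -> SlopeTestResult:
    """Student's t test of the OLS slope against 1 on n-2 df."""
    se = fit.se_slope if se_slope is None else se_slope
    if se <= 0:
        raise ValueError("slope standard error must be positive")
    if fit.n < 3:
        raise ValueError("need n >= 3")
    t = (fit.slope - 1.0) / se
    df = fit.n - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return SlopeTestResult(t=float(t), df=df, p=float(p))


def compare_slopes(fit1: RegressionFit, fit2: RegressionFit,
                   se1: float | None = None,
                   se2: float | None = None) -> SlopeTestResult:
    """Student's t comparison of two independent OLS slopes.

    t = (m1 - m2) / sqrt(se1^2 + se2^2) on n1 + n2 - 4 df.
    """
    s1 = fit1.se_slope if se1 is None else se1
    s2 = fit2.se_slope if se2 is None else se2
    if s1 <= 0 and s2 <= 0:
        raise ValueError("at least one slope standard error must be positive")
    t = (fit1.slope - fit2.slope) / np.sqrt(s1 ** 2 + s2 ** 2)
    df = fit1.n + fit2.n - 4
    p = 2.0 * stats.t.sf(abs(t), df)
    return SlopeTestResult(t=float(t), df=df, p=float(p))
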