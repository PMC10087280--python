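"""Correlation, OLS regression, data filters, and the coincidence test.

The coincidence test asks whether a culture calibration line and an
environmental calibration line are statistically the same, via a single
pooled dummy-variable regression

    index = intercept + d_intercept * culture
            + slope * parameter + d_slope * culture * parameter

where ``culture`` is 0 for environmental and 1 for culture observations.
If d_intercept is indistinguishable from 0 the datasets are *concurrent*
(same intercept); if d_slope is indistinguishable from 0 they are
*parallel* (same slope); both together make them *coincident* (the same
regression line); neither makes them *distinct*.  All p-values are
two-sided t-tests; no multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "RegressionResult",
    "CoincidenceResult",
    "pearson_test",
    "ols_fit",
    "multiple_ols",
    "coincidence_test",
    "remove_rmse_outliers",
    "filter_saturated",
    "subset_analysis",
    "drop_undefined_pairs",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass
class RegressionResult:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r2: float
    p_slope: float
    n: int
    rmse: float


@dataclass
class CoincidenceResult:
    slope: float
    intercept: float
    delta_slope: float
    delta_slope_se: float
    p_delta_slope: float
    delta_intercept: float
    delta_intercept_se: float
    p_delta_intercept: float
    n_env: int
    n_culture: int
    classification: frozenset = field(default_factory=frozenset)

    @property
    def coincident(self) -> bool:
        return "coincident" in self.classification


def _clean_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d non-finite pairs", dropped)
    return x[keep], y[keep]


def drop_undefined_pairs(x, y, defined=None) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-drop undefined index values (and non-finite entries)."""
    x = np.asarray(x, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    if defined is not None:
        y = np.where(np.asarray(defined, dtype=bool), y, np.nan)
    return _clean_xy(x, y)


def pearson_test(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x, y = _clean_xy(x, y)
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 finite pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n)


def ols_fit(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with intercept.

    Standard errors use the unbiased residual variance; rmse is
    sqrt(SSE / (n - 2)).
    """
    x, y = _clean_xy(x, y)
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 finite pairs, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("constant x: slope is not identified")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    sse = float(np.sum(fit.resid**2))
    return RegressionResult(
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        intercept=float(fit.params[0]),
        intercept_se=float(fit.bse[0]),
        r2=float(fit.rsquared),
        p_slope=float(fit.pvalues[1]),
        n=n,
        rmse=math.sqrt(sse / (n - 2)),
    )


def multiple_ols(y, predictors: dict[str, np.ndarray]):
    """Multivariable OLS with intercept; per-coefficient two-sided t-tests.

    Returns a DataFrame indexed by predictor name (plus 'intercept') with
    columns estimate / se / p.  Rank-deficient designs are rejected naming
    the collinear columns.
    """
    import pandas as pd

    names = list(predictors)
    X = np.column_stack([np.asarray(predictors[k], dtype=float) for k in names])
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    X, y = X[keep], y[keep]
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > {k + 1} observations, got {n}")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = []
        for j, name in enumerate(names):
            others = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(design):
                bad.append(name)
        raise ValueError(f"rank-deficient design; collinear columns: {bad or names}")
    fit = sm.OLS(y, design).fit()
    rows = ["intercept"] + names
    return pd.DataFrame(
        {"estimate": fit.params, "se": fit.bse, "p": fit.pvalues}, index=rows
    )


def coincidence_test(env_x, env_y, culture_x, culture_y, alpha: float = 0.05) -> CoincidenceResult:
    """Dummy-variable test of whether two calibration lines coincide.

    Fits the pooled interaction model and classifies per the rule above:
    p(d_intercept) > alpha -> concurrent, p(d_slope) > alpha -> parallel,
    both -> coincident, neither -> distinct.  A coefficient that is exactly
    zero with zero residual variance (duplicated data) is treated as
    indistinguishable from zero (p = 1).
    """
    env_x, env_y = _clean_xy(env_x, env_y)
    cul_x, cul_y = _clean_xy(culture_x, culture_y)
    if env_x.size < 3 or cul_x.size < 3:
        raise ValueError("each group needs n >= 3")
    if np.ptp(env_x) == 0 or np.ptp(cul_x) == 0:
        raise ValueError("constant x within a group")
    x = np.concatenate([env_x, cul_x])
    y = np.concatenate([env_y, cul_y])
    d = np.concatenate([np.zeros_like(env_x), np.ones_like(cul_x)])
    design = np.column_stack([np.ones_like(x), d, x, d * x])
    fit = sm.OLS(y, design).fit()
    params, bse, pvals = fit.params, fit.bse, fit.pvalues

    def _p(j: int) -> float:
        # degenerate zero-residual case: coefficient 0 with se 0
        if not np.isfinite(pvals[j]):
            return 1.0 if abs(params[j]) < 1e-12 else 0.0
        return float(pvals[j])

    p_dint, p_dslope = _p(1), _p(3)
    labels = set()
    if p_dint > alpha:
        labels.add("concurrent")
    if p_dslope > alpha:
        labels.add("parallel")
    if {"concurrent", "parallel"} <= labels:
        labels.add("coincident")
    if not labels:
        labels.add("distinct")
    return CoincidenceResult(
        slope=float(params[2]),
        intercept=float(params[0]),
        delta_slope=float(params[3]),
        delta_slope_se=float(bse[3]),
        p_delta_slope=p_dslope,
        delta_intercept=float(params[1]),
        delta_intercept_se=float(bse[1]),
        p_delta_intercept=p_dint,
        n_env=int(env_x.size),
        n_culture=int(cul_x.size),
        classification=frozenset(labels),
    )


def remove_rmse_outliers(x, y, k: float = 3.0):
    """Single-pass outlier removal against an OLS fit.

    Fits once and removes points whose absolute residual strictly exceeds
    ``k`` times the regression RMSE (a point at exactly k*RMSE is kept).
    Returns (kept_x, kept_y, removed_indices).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need n >= 4 for outlier screening")
    fit = ols_fit(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    removed = np.flatnonzero(np.abs(resid) > k * fit.rmse)
    keep = np.setdiff1d(np.arange(x.size), removed)
    if removed.size:
        logger.info("removed %d outliers beyond %g*RMSE", removed.size, k)
    return x[keep], y[keep], removed


def filter_saturated(values, saturation_value: float = 1.0, tol: float = 1e-9) -> np.ndarray:
    """Boolean mask keeping values that are NOT at the saturation ceiling.

    Index values equal to the saturation value (within ``tol``) carry no
    gradient information and are excluded from linear fits.
    """
    values = np.asarray(values, dtype=float)
    saturated = np.isfinite(values) & (np.abs(values - saturation_value) <= tol)
    if saturated.any():
        logger.info("filter_saturated: excluded %d saturated values", int(saturated.sum()))
    return ~saturated


def subset_analysis(x, y, subsets: dict[str, np.ndarray], alpha: float = 0.05) -> dict[str, dict]:
    """Pearson correlation per subset; OLS only where the correlation is significant.

    ``subsets`` maps a label to a boolean mask.  Subsets selecting fewer
    than 3 finite pairs are reported as not evaluable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out: dict[str, dict] = {}
    for label, mask in subsets.items():
        mask = np.asarray(mask, dtype=bool)
        xs, ys = drop_undefined_pairs(x[mask], y[mask])
        if xs.size < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
            out[label] = {"evaluable": False, "n": int(xs.size)}
            continue
        corr = pearson_test(xs, ys)
        row = {"evaluable": True, "n": corr.n, "correlation": corr, "regression": None}
        if corr.p < alpha:
            row["regression"] = ols_fit(xs, ys)
        out[label] = row
    return out
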