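"""Logistic growth-curve fitting and derived batch-culture kinetics.

Batch OD curves are fit to the three-parameter logistic

    OD(t) = K / (1 + ((K - n0) / n0) * exp(-mu * t))

with carrying capacity ``K`` (OD units), specific growth rate ``mu``
(per day) and initial density ``n0``.  No lag term is modeled.  Doubling
time is ln(2)/mu.  The generation count between inoculation and harvest is
log2(OD_final / OD_inoculum_contribution), and the inoculum's carryover
into the harvested biomass after n generations is 100 * 2^-n percent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .samples import GrowthCurve

__all__ = [
    "LogisticFit",
    "logistic_od",
    "fit_logistic",
    "doubling_time",
    "generation_count",
    "inoculum_fraction",
]

logger = logging.getLogger(__name__)


@dataclass
class LogisticFit:
    K: float
    mu: float
    n0: float
    rmse: float
    converged: bool
    message: str = ""

    def doubling_time(self, unit: str = "days") -> float:
        return doubling_time(self.mu, unit)


def logistic_od(t: np.ndarray, K: float, mu: float, n0: float) -> np.ndarray:
    """Evaluate the logistic growth model."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + ((K - n0) / n0) * np.exp(-mu * t))


def _initial_guess(t: np.ndarray, od: np.ndarray) -> tuple[float, float, float]:
    # K from the plateau, n0 from the first point, mu from the log-linear
    # slope over the early (below half-maximum) segment.
    K0 = float(np.max(od)) * 1.05
    n0 = float(od[0])
    early = od <= 0.5 * np.max(od)
    if early.sum() >= 2:
        coef = np.polyfit(t[early], np.log(od[early]), 1)
        mu0 = float(coef[0])
    else:
        mu0 = (np.log(od[-1]) - np.log(od[0])) / max(t[-1] - t[0], 1e-9)
    mu0 = max(mu0, 1e-3)
    return K0, mu0, n0


def fit_logistic(curve: GrowthCurve, p0: tuple[float, float, float] | None = None) -> LogisticFit:
    """Least-squares logistic fit of an OD time series.

    OD values <= 0 (sensor noise in logger streams) are dropped with a
    logged count before fitting.  Raises on fewer than 4 usable points or a
    monotonically decreasing series; reports ``converged=False`` with a
    diagnostic message when the optimizer fails.
    """
    keep = curve.od > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("fit_logistic: dropped %d non-positive OD values", dropped)
    t = curve.times[keep]
    od = curve.od[keep]
    if t.size < 4:
        raise ValueError(f"unfittable: need >= 4 positive OD points, got {t.size}")
    if np.all(np.diff(od) < 0):
        raise ValueError("monotonically decreasing OD series cannot be fit to growth")

    if p0 is None:
        p0 = _initial_guess(t, od)
    bounds = ([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf])
    try:
        popt, _ = curve_fit(logistic_od, t, od, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        return LogisticFit(
            K=math.nan, mu=math.nan, n0=math.nan, rmse=math.nan,
            converged=False, message=str(exc),
        )
    K, mu, n0 = (float(v) for v in popt)
    resid = od - logistic_od(t, K, mu, n0)
    rmse = float(np.sqrt(np.mean(resid**2)))
    ok = K > n0 > 0 and mu > 0
    return LogisticFit(K=K, mu=mu, n0=n0, rmse=rmse, converged=ok,
                       message="" if ok else "fit violates K > n0 > 0, mu > 0")


def doubling_time(mu: float, unit: str = "days") -> float:
    """ln(2)/mu, in days or hours; ``mu`` is per day and must be positive."""
    if mu <= 0:
        raise ValueError(f"growth rate must be positive, got {mu}")
    td = math.log(2.0) / mu
    if unit == "days":
        return td
    if unit == "hours":
        return td * 24.0
    raise ValueError(f"unknown unit {unit!r}; expected 'days' or 'hours'")


def generation_count(od_inoculum_contribution: float, od_final: float) -> float:
    """Number of doublings between inoculation and harvest: log2(final/inoculum)."""
    if od_inoculum_contribution <= 0 or od_final <= 0:
        raise ValueError("optical densities must be positive")
    if od_final < od_inoculum_contribution:
        raise ValueError("final OD must be >= inoculum contribution")
    return math.log2(od_final / od_inoculum_contribution)


def inoculum_fraction(n_generations: float) -> float:
    """Maximal inoculum carryover into harvested biomass, percent: 100 * 2^-n."""
    if n_generations < 0:
        raise ValueError("generation count must be >= 0")
    return 100.0 * 2.0 ** (-n_generations)
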