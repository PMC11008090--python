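"""Instrumental-drift detection and correction from a reference-standard series.

Over a two-hour kinetic run a spectrometer's response can drift; the bench
protocol therefore reads a reference-standard solution every 30 min.  If a
simple linear regression of reference absorbance on time has a slope that a
Student-t test finds significant, the whole absorbance record is corrected
by subtracting ``slope * t`` (an additive linear background, anchored at
t = 0).

:func:`linest` reports the full ten-field output of spreadsheet-style OLS
(slope, intercept, their standard errors, R^2, standard error of regression,
F statistic, residual df, regression and residual sums of squares) so the
drift report matches what a bench analyst sees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .experiment_io import AbsorbanceSample, KineticSeries, summarize_replicates

__all__ = [
    "RegressionResult",
    "DriftTestResult",
    "FTestResult",
    "linest",
    "fit_reference_drift",
    "slope_t_test",
    "intercept_t_test",
    "regression_f_test",
    "correct_drift",
]


@dataclass(frozen=True)
class RegressionResult:
    """Simple-linear-regression output (spreadsheet LINEST layout).

    slope/intercept with standard errors ``u_m``/``u_b``, coefficient of
    determination ``r_squared``, standard error of regression ``s_y``,
    F statistic, residual degrees of freedom ``df`` (= n - 2), and the
    regression / residual sums of squares.
    """

    slope: float
    intercept: float
    u_m: float
    u_b: float
    r_squared: float
    s_y: float
    f_stat: float
    df: int
    ss_reg: float
    ss_res: float

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("residual degrees of freedom must be >= 1")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared out of [0, 1]")
        if self.ss_reg < 0 or self.ss_res < 0:
            raise ValueError("sums of squares must be >= 0")


@dataclass(frozen=True)
class DriftTestResult:
    """Two-sided Student-t test of a regression coefficient against zero."""

    t_stat: float
    t_critical: float
    alpha: float
    significant: bool


class FTestResult(NamedTuple):
    f_stat: float
    f_critical: float
    significant: bool


def linest(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least-squares simple linear regression, all fields populated.

    Requires n >= 3 (so df >= 1) and non-constant x.  For a perfect line
    (zero residual sum of squares) the coefficient standard errors are 0
    and the F statistic is reported as infinite.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points (df would be < 1)")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("x values are all equal; slope undefined")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    syy = float(np.sum((y - y.mean()) ** 2))

    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    df = n - 2
    ss_res = max(syy - slope * sxy, 0.0)
    ss_reg = slope * sxy
    s_y = math.sqrt(ss_res / df)
    u_m = s_y / math.sqrt(sxx)
    u_b = s_y * math.sqrt(1.0 / n + x.mean() ** 2 / sxx)
    r_squared = 1.0 if syy == 0 else min(ss_reg / syy, 1.0)
    f_stat = math.inf if ss_res == 0 else (ss_reg / 1.0) / (ss_res / df)
    return RegressionResult(
        slope=slope, intercept=intercept, u_m=u_m, u_b=u_b,
        r_squared=r_squared, s_y=s_y, f_stat=f_stat, df=df,
        ss_reg=ss_reg, ss_res=ss_res,
    )


def fit_reference_drift(series: KineticSeries) -> RegressionResult:
    """Regress replicate-averaged reference absorbance on time.

    Replicates are averaged first so each reference read contributes one
    regression point (five half-hourly reads over two hours give df = 3).
    """
    if len(series.references) < 3:
        raise ValueError("need at least 3 reference reads to assess drift")
    t = [r.time for r in series.references]
    a = [summarize_replicates(r).mean for r in series.references]
    return linest(t, a)


def _coef_t_test(coef: float, se: float, df: int, alpha: float) -> DriftTestResult:
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    t_critical = float(stats.t.ppf(1 - alpha / 2, df))
    if se == 0:
        t_stat = 0.0 if coef == 0 else math.inf
    else:
        t_stat = coef / se
    return DriftTestResult(
        t_stat=t_stat, t_critical=t_critical, alpha=alpha,
        significant=abs(t_stat) > t_critical,
    )


def slope_t_test(reg: RegressionResult, alpha: float = 0.05) -> DriftTestResult:
    """Is the drift slope significantly non-zero?  t = slope / u_m."""
    return _coef_t_test(reg.slope, reg.u_m, reg.df, alpha)


def intercept_t_test(reg: RegressionResult, alpha: float = 0.05) -> DriftTestResult:
    """Is the intercept significantly non-zero?  t = intercept / u_b."""
    return _coef_t_test(reg.intercept, reg.u_b, reg.df, alpha)


def regression_f_test(reg: RegressionResult, alpha: float = 0.05) -> FTestResult:
    """Overall regression F test; for one predictor f_stat equals t_stat^2."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    f_critical = float(stats.f.ppf(1 - alpha, 1, reg.df))
    return FTestResult(f_stat=reg.f_stat, f_critical=f_critical,
                       significant=reg.f_stat > f_critical)


def correct_drift(
    series: KineticSeries,
    reg: RegressionResult,
    policy: str = "if_significant",
    alpha: float = 0.05,
) -> KineticSeries:
    """Remove the linear drift: every replicate at time t becomes A - slope*t.

    The correction is anchored at t = 0 (the calibration blank), applied
    identically to sample and reference reads.  Under policy
    ``"if_significant"`` the series is returned unchanged when the slope
    t-test does not reject at ``alpha``; policy ``"always"`` corrects
    unconditionally.
    """
    if policy not in ("always", "if_significant"):
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "if_significant" and not slope_t_test(reg, alpha).significant:
        return series

    def shift(sample: AbsorbanceSample) -> AbsorbanceSample:
        corrected = tuple(a - reg.slope * sample.time for a in sample.replicates)
        return AbsorbanceSample(time=sample.time, replicates=corrected,
                                kind=sample.kind)

    return KineticSeries(
        meta=series.meta,
        samples=tuple(shift(s) for s in series.samples),
        references=tuple(shift(r) for r in series.references),
    )
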