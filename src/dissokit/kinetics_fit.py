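"""Power-law (Korsmeyer–Peppas) release kinetics by multi-start NLLS.

The empirical release model

    Q(t) = K * t^n

describes the first ~60% of fractional release; ``n`` diagnoses the
transport mechanism (Fickian vs anomalous) and ``K`` scales with loading
and diffusivity.  The fit minimises the unweighted chi-square

    chi2(K, n) = sum_i (Q_i - K * t_i^n)^2

with a Levenberg-Marquardt iteration in (ln K, n) — the log
parameterisation keeps K positive — started from a log-linear OLS
initial guess plus a small grid of perturbed starts, so a local minimum
in the chi-square surface cannot masquerade as the answer.  Each start
runs until the chi-square change per accepted step falls below
``chi2_tol`` or ``max_iter`` is hit; all per-start results are retained
for surface diagnostics.  Residual randomness is judged by a
Wald-Wolfowitz runs test on residual signs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .curve_builder import DissolutionCurve

__all__ = [
    "PeppasFit",
    "StartResult",
    "FitConvergenceError",
    "select_fit_window",
    "loglinear_init",
    "default_starts",
    "fit_peppas",
    "runs_test",
]


class FitConvergenceError(RuntimeError):
    """All starts failed to converge; carries the per-start diagnostics."""

    def __init__(self, msg: str, start_results: list["StartResult"]):
        super().__init__(msg)
        self.start_results = start_results


class StartResult(NamedTuple):
    K0: float
    n0: float
    chi2: float
    K: float
    n: float
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class PeppasFit:
    """Fitted power-law parameters plus convergence and residual diagnostics."""

    K: float  # release constant, min^-n, fraction scale
    n: float  # release exponent
    chi2: float
    residuals: np.ndarray  # observed - fitted, fraction scale
    n_points: int
    starts_tried: int
    start_results: tuple[StartResult, ...]
    runs_test_p: float  # NaN when residuals are all ~0 (not applicable)
    K_se: float
    n_se: float

    def predict(self, times) -> np.ndarray:
        return self.K * np.power(np.asarray(times, dtype=float), self.n)


def select_fit_window(
    curve: DissolutionCurve, cutoff_percent: float = 60.0
) -> tuple[np.ndarray, np.ndarray]:
    """Points eligible for the power-law fit, on the fraction scale.

    Keeps points with Q <= cutoff (inclusive), t > 0 (the model passes
    through the origin by construction and ln t is undefined at 0), and
    no outlier flag.  Fewer than 3 survivors is an error: a two-parameter
    nonlinear fit needs more.
    """
    keep = (
        (curve.Q_percent <= cutoff_percent)
        & (curve.times > 0)
        & (~curve.outlier_flags)
    )
    if keep.sum() < 3:
        raise ValueError(
            f"insufficient points in {cutoff_percent:g}% window: "
            f"{int(keep.sum())} retained, need >= 3"
        )
    return curve.times[keep], curve.Q_percent[keep] / 100.0


def loglinear_init(times, Q_fractions) -> tuple[float, float]:
    """Initial (K0, n0) by OLS of ln Q on ln t (exact on noiseless data)."""
    t = np.asarray(times, dtype=float)
    q = np.asarray(Q_fractions, dtype=float)
    if np.any(q <= 0):
        raise ValueError("log-linear initialisation needs all Q > 0")
    if np.any(t <= 0):
        raise ValueError("log-linear initialisation needs all t > 0")
    slope, intercept = np.polyfit(np.log(t), np.log(q), 1)
    return float(math.exp(intercept)), float(slope)


def default_starts(times, Q_fractions) -> list[tuple[float, float]]:
    """Log-linear guess plus a 3x3 grid: K0*{0.5,1,2} x n0+{-.25,0,+.25}."""
    K0, n0 = loglinear_init(times, Q_fractions)
    return [
        (K0 * fk, n0 + dn)
        for fk in (0.5, 1.0, 2.0)
        for dn in (-0.25, 0.0, 0.25)
    ]


def _chi2(p: np.ndarray, t: np.ndarray, q: np.ndarray) -> float:
    r = math.exp(p[0]) * np.power(t, p[1]) - q
    return float(r @ r)


def _resid_jac(p: np.ndarray, t: np.ndarray, q: np.ndarray):
    model = math.exp(p[0]) * np.power(t, p[1])
    r = model - q
    jac = np.column_stack([model, model * np.log(t)])
    return r, jac


def _lm_from_start(
    t: np.ndarray, q: np.ndarray, K0: float, n0: float,
    max_iter: int, chi2_tol: float,
) -> tuple[np.ndarray, float, bool, int]:
    """Damped Gauss-Newton (Levenberg-Marquardt) from one start.

    Stops when an accepted step improves chi2 by less than ``chi2_tol``,
    when the damping parameter saturates (no downhill step exists within
    numerical resolution), or at ``max_iter`` accepted iterations; only
    the first two count as convergence.
    """
    p = np.array([math.log(K0), n0], dtype=float)
    lam = 1e-3
    chi2 = _chi2(p, t, q)
    eye = np.eye(2)
    for it in range(1, max_iter + 1):
        r, jac = _resid_jac(p, t, q)
        a = jac.T @ jac
        g = jac.T @ r
        stepped = False
        while lam < 1e14:
            damped = a + lam * np.diag(np.diag(a)) + 1e-300 * eye
            try:
                delta = np.linalg.solve(damped, -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            p_new = p + delta
            chi2_new = _chi2(p_new, t, q)
            if np.isfinite(chi2_new) and chi2_new <= chi2:
                p, improvement, chi2 = p_new, chi2 - chi2_new, chi2_new
                lam = max(lam / 3.0, 1e-12)
                stepped = True
                break
            lam *= 3.0
        if not stepped:
            return p, chi2, True, it  # damping saturated: at a minimum
        if improvement < chi2_tol:
            return p, chi2, True, it
    return p, chi2, False, max_iter


def fit_peppas(
    times,
    Q_fractions,
    starts: Sequence[tuple[float, float]] | None = None,
    max_iter: int = 500,
    chi2_tol: float = 1e-12,
) -> PeppasFit:
    """Multi-start NLLS fit of Q = K t^n; the best converged start wins.

    Standard errors come from the Jacobian at the optimum scaled by the
    residual variance (Gauss-Markov linearisation); ``K_se`` is mapped
    out of log space by the delta method.  Raises
    :class:`FitConvergenceError` with all per-start diagnostics if no
    start converges.
    """
    t = np.asarray(times, dtype=float)
    q = np.asarray(Q_fractions, dtype=float)
    if t.size != q.size or t.size < 3:
        raise ValueError("need >= 3 (time, Q) points of equal length")
    if np.any(t <= 0):
        raise ValueError("fit window must exclude t <= 0")
    if starts is None:
        starts = default_starts(t, q)
    if not starts:
        raise ValueError("starts must be non-empty")

    results: list[StartResult] = []
    for K0, n0 in starts:
        if K0 <= 0:
            raise ValueError("start values require K0 > 0")
        p, chi2, conv, n_iter = _lm_from_start(t, q, K0, n0, max_iter, chi2_tol)
        results.append(
            StartResult(K0=K0, n0=n0, chi2=chi2, K=math.exp(p[0]), n=float(p[1]),
                        converged=conv, n_iter=n_iter)
        )
    converged = [r for r in results if r.converged]
    if not converged:
        raise FitConvergenceError(
            f"none of {len(results)} starts converged", results
        )
    best = min(converged, key=lambda r: r.chi2)
    p_best = np.array([math.log(best.K), best.n])
    r, jac = _resid_jac(p_best, t, q)
    residuals = -r  # observed - fitted
    dof = t.size - 2
    if dof > 0 and best.chi2 > 0:
        s2 = best.chi2 / dof
        try:
            cov = s2 * np.linalg.inv(jac.T @ jac)
            se_lnK, se_n = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
        except np.linalg.LinAlgError:
            se_lnK = se_n = math.nan
    else:
        se_lnK = se_n = 0.0 if best.chi2 == 0 else math.nan

    return PeppasFit(
        K=best.K, n=best.n, chi2=best.chi2, residuals=residuals,
        n_points=int(t.size), starts_tried=len(results),
        start_results=tuple(results),
        runs_test_p=runs_test(residuals),
        K_se=best.K * se_lnK, n_se=se_n,
    )


def runs_test(residuals, zero_tol: float = 1e-12) -> float:
    """Wald-Wolfowitz runs test on residual signs; two-sided normal-approx p.

    Residuals within ``zero_tol`` of zero are dropped.  Returns NaN
    (not applicable) when everything is ~0, e.g. after a noiseless fit of
    the correct model.  All-one-sign residuals indicate systematic misfit
    and return the smallest positive float with a warning.
    """
    r = np.asarray(residuals, dtype=float)
    signs = np.sign(r[np.abs(r) > zero_tol])
    if signs.size == 0:
        return math.nan
    n_pos = int((signs > 0).sum())
    n_neg = int((signs < 0).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn("all residuals share one sign: systematic misfit")
        return float(np.finfo(float).tiny)
    n = n_pos + n_neg
    if n < 6:
        warnings.warn("runs test on < 6 signed residuals is unreliable")
    n_runs = int(1 + (np.diff(signs) != 0).sum())
    mean = 2.0 * n_pos * n_neg / n + 1.0
    var = (mean - 1.0) * (mean - 2.0) / (n - 1.0)
    if var <= 0:
        return math.nan
    z = (n_runs - mean) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))
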