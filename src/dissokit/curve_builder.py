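"""From corrected absorbance to a percent-dissolution curve.

The chain is: Beer's-law calibration (C = A / slope), the aliquot
mass-balance correction that restores the cumulative released
concentration as if no drug mass had been withdrawn at sampling,
normalisation to C_inf (either the observed plateau or the label dose),
and outlier screening with an iterated Grubbs test on moving-median
residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from pathlib import Path
from scipy import stats

from .experiment_io import ExperimentMeta, KineticSeries, summarize_replicates

__all__ = [
    "DissolutionCurve",
    "absorbance_to_concentration",
    "aliquot_correction",
    "percent_dissolution",
    "detect_outliers",
    "build_curve",
    "write_curve_csv",
    "read_curve_csv",
]


@dataclass(frozen=True)
class DissolutionCurve:
    """Percent-dissolved vs time with per-point uncertainty and outlier flags."""

    times: np.ndarray  # min
    Q_percent: np.ndarray
    Q_sd: np.ndarray  # per-point uncertainty, percent (NaN if unknown)
    outlier_flags: np.ndarray  # bool per point
    c_inf_mode: str  # "plateau" | "label_dose"
    meta: ExperimentMeta

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        q = np.asarray(self.Q_percent, dtype=float)
        sd = np.asarray(self.Q_sd, dtype=float)
        fl = np.asarray(self.outlier_flags, dtype=bool)
        if not (t.shape == q.shape == sd.shape == fl.shape) or t.ndim != 1:
            raise ValueError("times, Q_percent, Q_sd, outlier_flags must align")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(q)):
            raise ValueError("Q_percent must be finite")
        for name, arr in (("times", t), ("Q_percent", q), ("Q_sd", sd),
                          ("outlier_flags", fl)):
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return self.times.size


def absorbance_to_concentration(A, meta: ExperimentMeta):
    """Beer's law inversion C = A / calibration_slope (mg/mL).

    Negative absorbance (read noise around zero) passes through as
    negative concentration; non-finite input is an error.
    """
    a = np.asarray(A, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("absorbance must be finite")
    c = a / meta.calibration_slope
    return float(c) if np.isscalar(A) or a.ndim == 0 else c


def aliquot_correction(C, meta: ExperimentMeta):
    """Restore cumulative released concentration after aliquot withdrawals.

    Each assayed aliquot removes drug mass v*C_j from the vessel; the
    corrected series adds it back:

        C'_i = C_i + (v / V) * sum_{j < i} C_j

    which exactly inverts the withdraw-and-replenish mass balance.  With
    v = 0 this is the identity.
    """
    c = np.asarray(C, dtype=float)
    if c.ndim != 1:
        raise ValueError("concentration series must be 1-D")
    v, V = meta.aliquot_volume, meta.vessel_volume
    prior = np.concatenate(([0.0], np.cumsum(c)[:-1]))
    return c + (v / V) * prior


def percent_dissolution(
    times,
    C,
    meta: ExperimentMeta,
    mode: str = "plateau",
    plateau_points: int = 3,
    C_sd=None,
) -> DissolutionCurve:
    """Normalise a corrected concentration series to percent dissolved.

    ``mode="label_dose"`` uses C_inf = dose / vessel_volume (the tablet's
    label claim fully dissolved); ``mode="plateau"`` uses the mean of the
    last ``plateau_points`` corrected concentrations (the observed
    complete-dissolution level).  ``C_sd``, if given, is propagated as
    Q_sd = 100 * C_sd / C_inf.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(C, dtype=float)
    if mode == "label_dose":
        c_inf = meta.dose / meta.vessel_volume
    elif mode == "plateau":
        if c.size < plateau_points:
            raise ValueError("series shorter than plateau_points")
        c_inf = float(np.mean(c[-plateau_points:]))
    else:
        raise ValueError(f"unknown c_inf mode {mode!r}")
    if c_inf <= 0:
        raise ValueError(f"C_inf must be > 0, got {c_inf}")
    q = 100.0 * c / c_inf
    if C_sd is None:
        sd = np.full(t.shape, np.nan)
    else:
        sd = 100.0 * np.asarray(C_sd, dtype=float) / c_inf
    return DissolutionCurve(
        times=t, Q_percent=q, Q_sd=sd,
        outlier_flags=np.zeros(t.shape, dtype=bool),
        c_inf_mode=mode, meta=meta,
    )


def detect_outliers(curve: DissolutionCurve, alpha: float = 0.05) -> DissolutionCurve:
    """Flag spikes via an iterated Grubbs test on moving-median residuals.

    Residuals are taken from a centred moving median (window 5), a
    smoother a single spike cannot drag; on a strictly monotone curve the
    centred median equals the point itself, so clean curves have zero
    residuals everywhere the full window exists.  The first and last two
    points lack a full window and are never flagged.  Each Grubbs pass
    flags at most the single most extreme residual at two-sided level
    ``alpha``; passes repeat until no rejection.  Flagged points are kept
    in the curve but marked, so downstream stages decide what to exclude.
    """
    n = len(curve)
    if n < 5:
        raise ValueError("need at least 5 points for outlier screening")

    flags = curve.outlier_flags.copy()
    while True:
        # trend from the currently unflagged points only, so an already
        # flagged spike cannot displace its neighbours' medians
        idx = np.flatnonzero(~flags)
        q = pd.Series(curve.Q_percent[idx])
        trend = q.rolling(window=5, center=True, min_periods=5).median().to_numpy()
        resid = curve.Q_percent[idx] - trend
        valid = np.isfinite(resid)
        r = resid[valid]
        m = r.size
        if m < 3:
            break
        sd = r.std(ddof=1)
        if sd == 0:
            break
        g = np.abs(r - r.mean()) / sd
        i_max = int(np.argmax(g))
        t_val = stats.t.ppf(1 - alpha / (2 * m), m - 2)
        g_crit = ((m - 1) / math.sqrt(m)) * math.sqrt(
            t_val**2 / (m - 2 + t_val**2)
        )
        if g[i_max] > g_crit:
            flags[idx[np.flatnonzero(valid)[i_max]]] = True
        else:
            break
    return replace(curve, outlier_flags=flags)


def build_curve(
    series: KineticSeries,
    apply_aliquot_correction: bool = True,
    c_inf_mode: str = "plateau",
    plateau_points: int = 3,
    screen_outliers: bool = True,
    alpha: float = 0.05,
) -> DissolutionCurve:
    """Full series-to-curve pipeline on replicate-averaged absorbances.

    Replicates are averaged per timepoint; the standard error of that mean
    is propagated through the calibration and normalisation into Q_sd.
    """
    if not series.samples:
        raise ValueError("series has no sample reads")
    times = np.array([s.time for s in series.samples])
    summaries = [summarize_replicates(s) for s in series.samples]
    a_mean = np.array([s.mean for s in summaries])
    a_sem = np.array(
        [s.sd / math.sqrt(s.n) if s.n > 1 else np.nan for s in summaries]
    )
    c = absorbance_to_concentration(a_mean, series.meta)
    c_sd = a_sem / series.meta.calibration_slope
    if apply_aliquot_correction:
        c = aliquot_correction(c, series.meta)
    curve = percent_dissolution(
        times, c, series.meta, mode=c_inf_mode,
        plateau_points=plateau_points, C_sd=c_sd,
    )
    if screen_outliers and len(curve) >= 5:
        curve = detect_outliers(curve, alpha=alpha)
    return curve


def write_curve_csv(curve: DissolutionCurve, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_min": curve.times,
            "Q_percent": curve.Q_percent,
            "Q_sd": curve.Q_sd,
            "outlier_flag": curve.outlier_flags.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_curve_csv(path: str | Path, meta: ExperimentMeta | None = None,
                   c_inf_mode: str = "plateau") -> DissolutionCurve:
    df = pd.read_csv(path)
    return DissolutionCurve(
        times=df["time_min"].to_numpy(float),
        Q_percent=df["Q_percent"].to_numpy(float),
        Q_sd=df["Q_sd"].to_numpy(float),
        outlier_flags=df["outlier_flag"].to_numpy().astype(bool),
        c_inf_mode=c_inf_mode,
        meta=meta if meta is not None else ExperimentMeta(),
    )
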