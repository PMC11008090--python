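"""Model-independent dissolution-profile comparison: f1 and f2 factors.

The regulatory (Moore-Flanner) statistics compare a reference profile R
and a test profile T on a shared time grid:

    f1 = 100 * sum|R_t - T_t| / sum R_t            (difference factor)
    f2 = 50 * log10( 100 / sqrt(1 + mean (R_t - T_t)^2) )   (similarity)

Identical profiles give f1 = 0 and f2 = 100 exactly.  The regulatory
consistency call requires BOTH f1 < 15 and f2 > 50, strictly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .curve_builder import DissolutionCurve

__all__ = [
    "ProfilePair",
    "ComparisonResult",
    "pair_profiles",
    "difference_factor",
    "similarity_factor",
    "fda_consistency",
    "compare_curves",
]

F1_THRESHOLD = 15.0
F2_THRESHOLD = 50.0


@dataclass(frozen=True)
class ProfilePair:
    """Reference and test percent-dissolution values on one shared grid."""

    times: np.ndarray
    R: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        r = np.asarray(self.R, float)
        s = np.asarray(self.T, float)
        if not (t.shape == r.shape == s.shape) or t.ndim != 1:
            raise ValueError("times, R, T must be 1-D and aligned")
        if t.size < 3:
            raise ValueError("need at least 3 shared time points")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "R", r)
        object.__setattr__(self, "T", s)

    @property
    def n_points(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ComparisonResult:
    f1: float
    f2: float
    consistent: bool
    n_points_used: int


def pair_profiles(
    curve_R: DissolutionCurve,
    curve_T: DissolutionCurve,
    truncation: str = "all_points",
) -> ProfilePair:
    """Align two curves into a ProfilePair.

    The two grids must be identical — no silent interpolation, because
    resampling changes f2.  Points flagged as outliers in either curve are
    dropped from both.  ``truncation="fda_85_rule"`` keeps points up to and
    including the first at which both profiles exceed 85% dissolved.
    """
    if truncation not in ("all_points", "fda_85_rule"):
        raise ValueError(f"unknown truncation {truncation!r}")
    if not np.array_equal(curve_R.times, curve_T.times):
        raise ValueError(
            "time grids differ; resample upstream before profile comparison"
        )
    keep = ~(curve_R.outlier_flags | curve_T.outlier_flags)
    times = curve_R.times[keep]
    r = curve_R.Q_percent[keep]
    t = curve_T.Q_percent[keep]
    if truncation == "fda_85_rule":
        both_over = (r > 85.0) & (t > 85.0)
        if both_over.any():
            cut = int(np.argmax(both_over)) + 1  # keep first crossing point
            times, r, t = times[:cut], r[:cut], t[:cut]
    if times.size < 3:
        raise ValueError("fewer than 3 shared points after truncation")
    return ProfilePair(times=times, R=r, T=t)


def difference_factor(pair: ProfilePair) -> float:
    """f1 = 100 * sum|R - T| / sum R; percent average absolute difference."""
    denom = float(np.sum(pair.R))
    if denom <= 0:
        raise ValueError("reference profile sums to <= 0; f1 undefined")
    return 100.0 * float(np.sum(np.abs(pair.R - pair.T))) / denom


def similarity_factor(pair: ProfilePair) -> float:
    """f2 = 50 * log10(100 / sqrt(1 + mean squared difference))."""
    msd = float(np.mean((pair.R - pair.T) ** 2))
    return 50.0 * math.log10(100.0 / math.sqrt(1.0 + msd))


def fda_consistency(f1: float, f2: float, n_points_used: int = 0) -> ComparisonResult:
    """Regulatory call: consistent iff f1 < 15 AND f2 > 50 (strict)."""
    if not (math.isfinite(f1) and math.isfinite(f2)):
        raise ValueError("f1 and f2 must be finite")
    return ComparisonResult(
        f1=f1, f2=f2,
        consistent=(f1 < F1_THRESHOLD and f2 > F2_THRESHOLD),
        n_points_used=n_points_used,
    )


def compare_curves(
    curve_R: DissolutionCurve,
    curve_T: DissolutionCurve,
    truncation: str = "all_points",
) -> ComparisonResult:
    """Pair, score, and decide in one call (reference = first argument)."""
    pair = pair_profiles(curve_R, curve_T, truncation=truncation)
    return fda_consistency(
        difference_factor(pair), similarity_factor(pair), pair.n_points
    )
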