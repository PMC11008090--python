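"""Forward simulation of the bench dissolution protocol.

The generator reproduces the full measurement chain of a stirred-vessel
(USP-basket-style) dissolution run so that every downstream stage can be
exercised without real data:

1. a true release curve ``Q(t)`` — either a capped power law
   ``min(K t^n, 1)`` (the exact-recovery regime for oracle tests) or a
   Weibull curve ``1 - exp(-(t/tau)^beta)`` (realistic sigmoidal shape
   with a plateau);
2. the aliquot mass balance: every ``sampling_interval`` minutes an
   aliquot of volume ``v`` is withdrawn for assay and replaced with fresh
   medium, so the vessel concentration at sampling time ``t_i`` is
   ``C_i = (dose * Q(t_i) - sum_{j<i} v * C_j) / V``;
3. Beer's-law readout with linear instrumental drift and additive
   Gaussian read noise: each replicate read is
   ``slope_cal * C_i + m_drift * t_i + N(0, noise_sd)``;
4. a reference-standard series read every ``reference_interval`` minutes:
   ``A_ref(t) = A_ref0 + m_drift * t + N(0, noise_sd)``;
5. optional outlier spikes: a fixed absorbance offset added (after
   noise) to every replicate of a named sampling time, emulating a
   contaminated or scattering aliquot.

Defaults mirror the bench protocol: 900 mL medium, 5 mL aliquot every
5 min for 120 min, 10 replicate reads per aliquot, reference standard
every 30 min, 200 mg dose, drift 6e-5 AU/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .experiment_io import (
    AbsorbanceSample,
    ExperimentMeta,
    KineticSeries,
    SampleKind,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "true_release_fraction",
    "simulate_experiment",
    "write_ground_truth_csv",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the forward model; defaults are the bench protocol."""

    model: str = "weibull"  # "power_law_capped" | "weibull"
    K: float = 0.12  # release constant, min^-n (power law)
    n: float = 0.5  # release exponent (power law)
    tau: float = 40.0  # Weibull timescale, min
    beta: float = 0.9  # Weibull shape
    dose: float = 200.0  # mg
    vessel_volume: float = 900.0  # mL
    aliquot_volume: float = 5.0  # mL
    calibration_slope: float = 2.0  # AU per (mg/mL)
    drift_slope: float = 6e-5  # AU/min
    drift_intercept_ref: float = 0.4335  # reference absorbance at t=0, AU
    noise_sd: float = 0.003  # AU per replicate read
    n_replicates: int = 10
    sampling_interval: float = 5.0  # min
    duration: float = 120.0  # min
    reference_interval: float = 30.0  # min
    outliers: tuple[tuple[float, float], ...] = ()  # (time_min, offset_AU)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "outliers", tuple(tuple(o) for o in self.outliers))
        if self.model not in ("power_law_capped", "weibull"):
            raise ValueError(f"unknown model {self.model!r}")
        for name in ("K", "tau", "beta", "dose", "vessel_volume",
                     "calibration_slope", "sampling_interval", "duration",
                     "reference_interval"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.n <= 1.5):
            raise ValueError("release exponent n must lie in (0, 1.5]")
        if self.aliquot_volume < 0 or self.aliquot_volume >= self.vessel_volume:
            raise ValueError("aliquot_volume must be >= 0 and < vessel_volume")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.duration < self.sampling_interval:
            raise ValueError("duration must be >= sampling_interval")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def meta(self) -> ExperimentMeta:
        return ExperimentMeta(
            vessel_volume=self.vessel_volume,
            aliquot_volume=self.aliquot_volume,
            dose=self.dose,
            calibration_slope=self.calibration_slope,
            sampling_interval=self.sampling_interval,
            medium_mass=self.vessel_volume,  # water at 1 g/mL
        )


@dataclass(frozen=True)
class GroundTruth:
    """Truth channel for recovery tests: pre-noise signal at each sampling time."""

    times: np.ndarray  # min
    Q_true: np.ndarray  # released fraction in [0, 1]
    C_vessel_true: np.ndarray  # mg/mL after the aliquot mass balance
    A_true: np.ndarray  # deterministic absorbance (incl. drift), AU


def true_release_fraction(config: SimulationConfig, t: float | np.ndarray):
    """Released fraction Q(t) of the configured release model.

    ``power_law_capped`` returns ``min(K t^n, 1)``; ``weibull`` returns
    ``1 - exp(-(t/tau)^beta)``.  Both are 0 at t = 0.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    if config.model == "power_law_capped":
        q = np.minimum(config.K * np.power(t_arr, config.n), 1.0)
    else:
        q = 1.0 - np.exp(-np.power(t_arr / config.tau, config.beta))
    return float(q) if np.isscalar(t) or t_arr.ndim == 0 else q


def simulate_experiment(config: SimulationConfig) -> tuple[KineticSeries, GroundTruth]:
    """Run the forward model; identical config (incl. seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    n_pts = int(round(config.duration / config.sampling_interval))
    times = config.sampling_interval * np.arange(1, n_pts + 1)

    q_true = true_release_fraction(config, times)

    # aliquot mass balance: C_i = (dose*Q_i - sum_{j<i} v*C_j) / V
    v, V = config.aliquot_volume, config.vessel_volume
    c_true = np.empty(n_pts)
    removed = 0.0  # cumulative drug mass carried out by past aliquots, mg
    for i in range(n_pts):
        c_true[i] = (config.dose * q_true[i] - removed) / V
        removed += v * c_true[i]

    a_true = config.calibration_slope * c_true + config.drift_slope * times

    outlier_map = {float(t): float(off) for t, off in config.outliers}
    samples = []
    for i, t in enumerate(times):
        reps = a_true[i] + rng.normal(0.0, config.noise_sd, config.n_replicates)
        if float(t) in outlier_map:
            reps = reps + outlier_map[float(t)]
        samples.append(AbsorbanceSample(time=float(t), replicates=tuple(reps)))

    ref_times = np.arange(0.0, config.duration + 1e-9, config.reference_interval)
    references = []
    for t in ref_times:
        level = config.drift_intercept_ref + config.drift_slope * t
        reps = level + rng.normal(0.0, config.noise_sd, config.n_replicates)
        references.append(
            AbsorbanceSample(time=float(t), replicates=tuple(reps),
                             kind=SampleKind.REFERENCE)
        )

    series = KineticSeries(meta=config.meta(), samples=tuple(samples),
                           references=tuple(references))
    truth = GroundTruth(times=times, Q_true=q_true, C_vessel_true=c_true,
                        A_true=a_true)
    return series, truth


def write_ground_truth_csv(truth: GroundTruth, path: str | Path) -> Path:
    """Persist the truth channel (times, Q_true, C_vessel_true, A_true)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("time_min,Q_true,C_vessel_true,A_true\n")
        for t, q, c, a in zip(truth.times, truth.Q_true,
                              truth.C_vessel_true, truth.A_true):
            fh.write(f"{t!r},{q!r},{c!r},{a!r}\n")
    return path
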