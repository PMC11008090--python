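"""End-to-end orchestration: simulate or load, correct drift, build the
curve, fit the power law, and (optionally) compare two runs.

Every artifact is regenerable from the config plus seed alone; reports
are JSON with sorted keys so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import curve_builder, drift_analysis, kinetics_fit, profile_compare
from .experiment_io import KineticSeries, read_kinetics_csv, write_kinetics_csv
from .synthetic_experiment import (
    SimulationConfig,
    simulate_experiment,
    write_ground_truth_csv,
)

log = logging.getLogger("dissokit")

__all__ = ["PipelineConfig", "RunArtifacts", "run_single", "run_compare"]


@dataclass(frozen=True)
class PipelineConfig:
    """One analysis run: where the data come from and how each stage behaves."""

    mode: str = "simulate"  # "simulate" | "load"
    input_path: str | None = None  # required in load mode
    sim: SimulationConfig | None = None  # required in simulate mode
    alpha: float = 0.05
    drift_policy: str = "if_significant"  # "always" | "if_significant"
    c_inf_mode: str = "plateau"
    plateau_points: int = 3
    aliquot_correction: bool = True
    screen_outliers: bool = True
    fit_cutoff_percent: float = 60.0
    truncation: str = "all_points"
    outdir: str = "dissokit_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "load" and not self.input_path:
            raise ValueError("load mode requires input_path")
        if self.mode == "simulate" and self.sim is None:
            object.__setattr__(self, "sim", SimulationConfig(seed=self.seed))


@dataclass
class RunArtifacts:
    """In-memory results plus the paths of everything written."""

    series: KineticSeries
    corrected: KineticSeries
    regression: drift_analysis.RegressionResult
    drift_test: drift_analysis.DriftTestResult
    f_test: drift_analysis.FTestResult
    curve: curve_builder.DissolutionCurve
    fit: kinetics_fit.PeppasFit
    paths: dict[str, str] = field(default_factory=dict)


def _json_safe(value):
    if isinstance(value, float):
        if math.isnan(value):
            return "NaN"
        if math.isinf(value):
            return "Infinity" if value > 0 else "-Infinity"
        return value
    if isinstance(value, (np.floating, np.integer)):
        return _json_safe(float(value))
    if isinstance(value, np.ndarray):
        return [_json_safe(v) for v in value.tolist()]
    if isinstance(value, (list, tuple)):
        return [_json_safe(v) for v in value]
    if isinstance(value, dict):
        return {k: _json_safe(v) for k, v in value.items()}
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return _json_safe(dataclasses.asdict(value))
    return value


def _write_json(obj, path: Path) -> Path:
    with path.open("w") as fh:
        json.dump(_json_safe(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def run_single(config: PipelineConfig) -> RunArtifacts:
    """Execute one full analysis; writes CSV/JSON artifacts plus a run log."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    log_lines: list[str] = []

    def note(msg: str) -> None:
        log.info(msg)
        log_lines.append(msg)

    t0 = time.perf_counter()
    if config.mode == "simulate":
        series, truth = simulate_experiment(config.sim)
        paths["raw_csv"] = str(write_kinetics_csv(series, outdir / "raw.csv"))
        paths["ground_truth_csv"] = str(
            write_ground_truth_csv(truth, outdir / "ground_truth.csv")
        )
        note(f"simulated {len(series.samples)} sample reads, "
             f"{len(series.references)} reference reads (seed {config.sim.seed})")
    else:
        series = read_kinetics_csv(config.input_path)
        note(f"loaded {config.input_path}: {len(series.samples)} sample reads, "
             f"{len(series.references)} reference reads")

    reg = drift_analysis.fit_reference_drift(series)
    drift_test = drift_analysis.slope_t_test(reg, config.alpha)
    f_test = drift_analysis.regression_f_test(reg, config.alpha)
    corrected = drift_analysis.correct_drift(
        series, reg, policy=config.drift_policy, alpha=config.alpha
    )
    note(
        f"drift slope {reg.slope:.3e} AU/min, t = {drift_test.t_stat:.3f} vs "
        f"t_crit = {drift_test.t_critical:.3f} -> "
        f"{'significant, corrected' if drift_test.significant else 'not significant'}"
    )
    paths["corrected_csv"] = str(
        write_kinetics_csv(corrected, outdir / "corrected.csv")
    )
    paths["drift_report_json"] = str(
        _write_json(
            {"regression": reg, "slope_t_test": drift_test,
             "f_test": f_test._asdict(), "policy": config.drift_policy},
            outdir / "drift_report.json",
        )
    )

    curve = curve_builder.build_curve(
        corrected,
        apply_aliquot_correction=config.aliquot_correction,
        c_inf_mode=config.c_inf_mode,
        plateau_points=config.plateau_points,
        screen_outliers=config.screen_outliers,
        alpha=config.alpha,
    )
    n_flagged = int(curve.outlier_flags.sum())
    note(f"curve built: {len(curve)} points, {n_flagged} flagged as outliers, "
         f"C_inf mode {config.c_inf_mode}")
    paths["curve_csv"] = str(
        curve_builder.write_curve_csv(curve, outdir / "curve.csv")
    )

    t_fit, q_fit = kinetics_fit.select_fit_window(curve, config.fit_cutoff_percent)
    note(f"fit window (<= {config.fit_cutoff_percent:g}%): {t_fit.size} points")
    fit = kinetics_fit.fit_peppas(t_fit, q_fit)
    winner = min(
        (r for r in fit.start_results if r.converged), key=lambda r: r.chi2
    )
    note(
        f"Peppas fit: K = {fit.K:.6g} min^-n, n = {fit.n:.4f}, "
        f"chi2 = {fit.chi2:.3e}; winning start (K0, n0) = "
        f"({winner.K0:.4g}, {winner.n0:.4g}) of {fit.starts_tried} tried"
    )
    paths["fit_json"] = str(
        _write_json(
            {
                "K": fit.K, "n": fit.n, "chi2": fit.chi2,
                "K_se": fit.K_se, "n_se": fit.n_se,
                "n_points": fit.n_points, "starts_tried": fit.starts_tried,
                "runs_test_p": fit.runs_test_p,
                "residuals": fit.residuals,
                "start_results": [r._asdict() for r in fit.start_results],
            },
            outdir / "fit.json",
        )
    )
    fitted = fit.predict(t_fit)
    with (outdir / "fitted_curve.csv").open("w") as fh:
        fh.write("time_min,observed,fitted,residual\n")
        for t, obs, mod in zip(t_fit, q_fit, fitted):
            fh.write(f"{t!r},{obs!r},{mod!r},{obs - mod!r}\n")
    paths["fitted_curve_csv"] = str(outdir / "fitted_curve.csv")

    note(f"run complete in {time.perf_counter() - t0:.2f} s")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    paths["log"] = str(outdir / "run.log")
    return RunArtifacts(
        series=series, corrected=corrected, regression=reg,
        drift_test=drift_test, f_test=f_test, curve=curve, fit=fit,
        paths=paths,
    )


def run_compare(
    config: PipelineConfig,
    run_A: RunArtifacts,
    run_B: RunArtifacts,
    outdir: str | Path | None = None,
) -> profile_compare.ComparisonResult:
    """Score run_A (reference) against run_B (test) with f1/f2."""
    result = profile_compare.compare_curves(
        run_A.curve, run_B.curve, truncation=config.truncation
    )
    log.info(
        "f1 = %.2f (threshold < %g), f2 = %.2f (threshold > %g) -> %s",
        result.f1, profile_compare.F1_THRESHOLD,
        result.f2, profile_compare.F2_THRESHOLD,
        "consistent" if result.consistent else "NOT consistent",
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_json(
            {
                "f1": result.f1, "f2": result.f2,
                "f1_threshold": profile_compare.F1_THRESHOLD,
                "f2_threshold": profile_compare.F2_THRESHOLD,
                "consistent": result.consistent,
                "n_points_used": result.n_points_used,
                "truncation": config.truncation,
            },
            outdir / "comparison.json",
        )
    return result
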