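import math

import numpy as np
import pytest
from scipy import stats

from dissokit.drift_analysis import (
    correct_drift,
    fit_reference_drift,
    intercept_t_test,
    linest,
    regression_f_test,
    slope_t_test,
)
from dissokit.experiment_io import summarize_replicates
from dissokit.synthetic_experiment import SimulationConfig, simulate_experiment


def ols_oracle(x, y):
    """Textbook closed-form OLS, independent of linest's code path."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    sxx = ((x - x.mean()) ** 2).sum()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - slope * x - intercept
    ss_res = (resid**2).sum()
    syy = ((y - y.mean()) ** 2).sum()
    df = n - 2
    s_y = math.sqrt(ss_res / df)
    return {
        "slope": slope,
        "intercept": intercept,
        "u_m": s_y / math.sqrt(sxx),
        "u_b": s_y * math.sqrt(1 / n + x.mean() ** 2 / sxx),
        "r_squared": 1 - ss_res / syy,
        "s_y": s_y,
        "df": df,
        "ss_res": ss_res,
        "ss_reg": syy - ss_res,
    }


class TestLinest:
    def test_perfect_line(self):
        x = np.arange(5.0)
        reg = linest(x, 2 * x + 1)
        assert reg.slope == pytest.approx(2) and reg.intercept == pytest.approx(1)
        assert reg.r_squared == 1.0 and reg.ss_res == 0.0
        assert math.isinf(reg.f_stat) and reg.u_m == 0.0

    def test_noiseless_drift_reconstruction(self):
        t = np.arange(0.0, 121.0, 30.0)
        reg = linest(t, 0.4335 + 6e-5 * t)
        assert reg.slope == pytest.approx(6e-5, rel=1e-10)
        assert reg.intercept == pytest.approx(0.4335, rel=1e-10)
        assert reg.df == 3

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_closed_form_oracle(self, rng, trial):
        n = int(rng.integers(3, 12))
        x = rng.normal(size=n) * 10
        while np.allclose(x, x[0]):
            x = rng.normal(size=n) * 10
        y = rng.normal(size=n)
        reg = linest(x, y)
        o = ols_oracle(x, y)
        for field in ("slope", "intercept", "u_m", "u_b", "s_y",
                      "ss_res", "ss_reg"):
            assert getattr(reg, field) == pytest.approx(o[field], rel=1e-9, abs=1e-12)
        assert reg.r_squared == pytest.approx(o["r_squared"], rel=1e-9)
        assert reg.df == o["df"]

    def test_f_consistency_invariant(self, rng):
        x = rng.normal(size=8)
        y = 0.3 * x + rng.normal(size=8)
        reg = linest(x, y)
        assert reg.f_stat == pytest.approx(
            (reg.ss_reg / 1.0) / (reg.ss_res / reg.df), rel=1e-12
        )

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            linest([1.0, 2.0], [1.0, 2.0])

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="all equal"):
            linest([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])


class TestHypothesisTests:
    def test_t_critical_df3(self):
        reg = linest(np.arange(5.0), np.arange(5.0) + [0, 1e-3, 0, -1e-3, 0])
        res = slope_t_test(reg, alpha=0.05)
        assert res.t_critical == pytest.approx(3.182, abs=5e-4)

    def test_reported_drift_scenario_significant(self):
        # slope t of 5.845 against t_crit 3.182 (df = 3, 95%) must reject
        t_crit = float(stats.t.ppf(0.975, 3))
        assert 5.845 > t_crit

    def test_zero_slope_never_significant(self):
        # y chosen so that Sxy = 0 exactly: slope = 0, t = 0
        t = np.arange(0.0, 121.0, 30.0)
        y = 0.4335 + np.array([1, -1, 0, -1, 1]) * 1e-4
        reg = linest(t, y)
        assert reg.slope == 0.0
        for alpha in (0.01, 0.05, 0.2):
            res = slope_t_test(reg, alpha)
            assert res.t_stat == 0.0 and not res.significant

    def test_intercept_t_table_values(self):
        # intercept 0.4335 with u_b 0.0007 gives t ~ 619.3: overwhelmingly
        # significant at df = 3
        t_stat = 0.4335 / 0.0007
        assert t_stat == pytest.approx(619.3, abs=0.05)
        t = np.arange(0.0, 121.0, 30.0)
        reg = linest(t, 0.4335 + 6e-5 * t + np.array([1, -1, 1, -1, 1]) * 7e-4)
        res = intercept_t_test(reg)
        assert res.significant and res.t_stat > 100

    def test_t_quantile_matches_oracle(self, rng):
        t = np.arange(0.0, 121.0, 30.0)
        reg = linest(t, rng.normal(size=5))
        for alpha in (0.01, 0.05, 0.1):
            res = slope_t_test(reg, alpha)
            assert res.t_critical == pytest.approx(
                float(stats.t.ppf(1 - alpha / 2, reg.df)), rel=1e-12
            )

    def test_f_equals_t_squared(self, rng):
        x = rng.normal(size=7)
        y = 0.5 * x + rng.normal(size=7) * 0.3
        reg = linest(x, y)
        t_res = slope_t_test(reg)
        f_res = regression_f_test(reg)
        assert f_res.f_stat == pytest.approx(t_res.t_stat**2, rel=1e-9)

    def test_f_critical_is_squared_t_critical(self):
        t = np.arange(0.0, 121.0, 30.0)
        reg = linest(t, np.array([0.1, 0.3, 0.2, 0.5, 0.4]))
        f_res = regression_f_test(reg, alpha=0.05)
        assert f_res.f_critical == pytest.approx(3.182**2, abs=0.01)

    def test_perfect_line_f_significant(self):
        reg = linest(np.arange(5.0), 2 * np.arange(5.0) + 1)
        assert regression_f_test(reg).significant


class TestCorrectDrift:
    def test_pure_drift_reference_constant_after_correction(self):
        cfg = SimulationConfig(noise_sd=0.0, drift_slope=6e-5)
        series, _ = simulate_experiment(cfg)
        reg = fit_reference_drift(series)
        corrected = correct_drift(series, reg, policy="always")
        levels = [summarize_replicates(r).mean for r in corrected.references]
        np.testing.assert_allclose(levels, cfg.drift_intercept_ref, rtol=1e-12)

    def test_zero_slope_identity(self, bench_series):
        reg = fit_reference_drift(bench_series)
        reg0 = type(reg)(slope=0.0, intercept=reg.intercept, u_m=reg.u_m,
                         u_b=reg.u_b, r_squared=reg.r_squared, s_y=reg.s_y,
                         f_stat=reg.f_stat, df=reg.df, ss_reg=reg.ss_reg,
                         ss_res=reg.ss_res)
        assert correct_drift(bench_series, reg0, policy="always") == bench_series

    def test_paired_simulation_oracle(self):
        # correcting a noiseless drifted run must reproduce the driftless
        # run of the same seed to machine precision
        drifted, _ = simulate_experiment(
            SimulationConfig(noise_sd=0.0, drift_slope=6e-5, seed=7)
        )
        driftless, _ = simulate_experiment(
            SimulationConfig(noise_sd=0.0, drift_slope=0.0, seed=7)
        )
        corrected = correct_drift(drifted, fit_reference_drift(drifted),
                                  policy="always")
        for c, d in zip(corrected.samples, driftless.samples):
            np.testing.assert_allclose(c.replicates, d.replicates, atol=1e-12)

    def test_if_significant_policy_skips_when_no_drift(self):
        series, _ = simulate_experiment(
            SimulationConfig(drift_slope=0.0, seed=123)
        )
        reg = fit_reference_drift(series)
        if not slope_t_test(reg).significant:
            assert correct_drift(series, reg, policy="if_significant") == series

    def test_idempotent_after_correction(self):
        series, _ = simulate_experiment(SimulationConfig(seed=5))
        reg = fit_reference_drift(series)
        once = correct_drift(series, reg, policy="always")
        refit = fit_reference_drift(once)
        assert abs(refit.slope) < 1e-12
        assert correct_drift(once, refit, policy="if_significant") == once


class TestCalibration:
    def test_type_one_error_rate(self):
        # no drift: the slope test at alpha 0.05 should reject ~5% of runs
        rejections = 0
        n_reps = 600
        for s in range(n_reps):
            series, _ = simulate_experiment(
                SimulationConfig(seed=50_000 + s, drift_slope=0.0)
            )
            rejections += slope_t_test(fit_reference_drift(series)).significant
        assert 0.03 <= rejections / n_reps <= 0.07

    def test_power_at_table_scale(self):
        # drift 6e-5 AU/min against replicate-mean noise ~9.5e-4 AU: the
        # detected-drift regime; rejection should be the norm
        rejections = 0
        n_reps = 200
        for s in range(n_reps):
            series, _ = simulate_experiment(
                SimulationConfig(seed=80_000 + s, drift_slope=6e-5,
                                 noise_sd=0.003)
            )
            rejections += slope_t_test(fit_reference_drift(series)).significant
        assert rejections / n_reps > 0.9
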