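# dissokit

Analysis pipeline for **in vitro drug-dissolution testing** monitored by
single-wavelength UV-vis absorbance — the bench protocol in which a solid
oral dosage form (e.g. a 200 mg naproxen sodium tablet) dissolves in a
stirred 900 mL vessel, a 5 mL aliquot is withdrawn and replenished every
5 min for two hours, each aliquot is read 10 times at 329 nm, and a
reference-standard solution is read every 30 min to track instrumental
drift.

The package takes such an absorbance log (real or simulated) through the
full analysis a dissolution scientist performs:

1. **Drift detection and correction** — simple linear regression of the
   reference-standard absorbance on time (full spreadsheet-style output:
   slope ± u_m, intercept ± u_b, R², S_y, F, df, sums of squares), a
   Student-t test of the slope, and subtraction of the fitted linear
   background when significant.
2. **Curve building** — Beer's-law calibration C = A/(εb), the aliquot
   mass-balance correction
   C′ᵢ = Cᵢ + (v/V)·Σ_{j<i} Cⱼ that restores the cumulative released
   concentration, normalisation to C∞ (observed plateau or label dose),
   and Grubbs-based outlier screening.
3. **Kinetic modeling** — the Korsmeyer–Peppas power law
   **Q(t) = K·tⁿ**, valid for the first ~60 % of release, fitted by
   multi-start nonlinear least squares (Levenberg–Marquardt in
   (ln K, n)) with explicit Δχ² stopping, per-start χ² diagnostics, and a
   Wald–Wolfowitz runs test of residual randomness.
4. **Profile comparison** — the regulatory model-independent factors
   f₁ = 100·Σ|R−T|/ΣR and f₂ = 50·log₁₀(100/√(1+MSD)), with the FDA
   consistency call f₁ < 15 **and** f₂ > 50.

A forward simulator (`dissokit.synthetic_experiment`) generates the whole
protocol — release curve, withdrawal mass balance, drift, read noise,
outlier spikes — so every stage is testable without bench data, including
exact-recovery regimes.

## Worked example

```python
from dissokit import (SimulationConfig, simulate_experiment,
                      fit_reference_drift, slope_t_test, correct_drift,
                      build_curve, select_fit_window, fit_peppas,
                      compare_curves)

series, truth = simulate_experiment(SimulationConfig(seed=3))
reg = fit_reference_drift(series)
t = slope_t_test(reg)
print(f"drift slope {reg.slope:.2e} AU/min, t = {t.t_stat:.3f} "
      f"vs t_crit = {t.t_critical:.3f} -> significant: {t.significant}")

curve = build_curve(correct_drift(series, reg))
times, q = select_fit_window(curve)          # Q <= 60 %, t > 0, unflagged
fit = fit_peppas(times, q)
print(f"K = {fit.K:.4f} min^-n, n = {fit.n:.3f}, chi2 = {fit.chi2:.2e}")

other = build_curve(correct_drift(*(lambda s: (s, fit_reference_drift(s)))(
    simulate_experiment(SimulationConfig(seed=4))[0])))
res = compare_curves(curve, other)
print(f"f1 = {res.f1:.2f}, f2 = {res.f2:.2f}, consistent = {res.consistent}")
```

prints

```
drift slope 6.04e-05 AU/min, t = 11.763 vs t_crit = 3.182 -> significant: True
K = 0.0525 min^-n, n = 0.712, chi2 = 3.45e-04
f1 = 0.48, f2 = 98.09, consistent = True
```

The drift slope of ~6×10⁻⁵ AU/min is detected (t well above the 95 %
critical value 3.182 at df = 3) and removed; the fitted exponent
n ≈ 0.71 indicates anomalous (non-Fickian) transport over the 60 %
window of this sigmoidal release curve; the two replicate runs are
deemed consistent (f₁ far below 15, f₂ far above 50).

The same pipeline is available from the shell:

```bash
dissokit simulate --seed 1 --out run.csv
dissokit analyze run.csv --outdir out/
dissokit all --seed 1 --outdir both/   # two replicate runs + f1/f2
```

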