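# Methods

## The measurement model

A dissolution run monitors the concentration of drug released from a
tablet into a stirred vessel by withdrawing a small aliquot at fixed
intervals and reading its absorbance at a single wavelength.  The
package models the full signal chain:

    A(t_i) = εb · C(t_i) + m·t_i + ε_read,   ε_read ~ N(0, σ²)

where `εb` is the Beer's-law calibration slope (AU per mg/mL), `m` a
linear instrumental drift (AU/min), and σ the per-read photometric
noise.  The vessel concentration follows the withdraw-and-replenish
mass balance: with dose `D`, vessel volume `V` and aliquot volume `v`,

    C_i = ( D·Q(t_i) − Σ_{j<i} v·C_j ) / V

because every past aliquot carried drug mass `v·C_j` out of the vessel
before fresh medium restored the volume.  `Q(t)` is the true released
fraction.

### Release models in the simulator

- `power_law_capped`: Q(t) = min(K·tⁿ, 1).  This is the model the fitter
  assumes, so noiseless data from it admits *exact* parameter recovery —
  the end-to-end oracle regime.
- `weibull`: Q(t) = 1 − exp(−(t/τ)^β).  A realistic sigmoidal curve
  with a plateau; the power law is only a local approximation of it, as
  with real tablets.

Simulator defaults are the bench protocol: V = 900 mL (water filled by
mass, 900 g at 1 g/mL), v = 5 mL every 5 min for 120 min, 10 replicate
reads per aliquot, reference standard every 30 min, dose 200 mg,
wavelength 329 nm, drift m = 6×10⁻⁵ AU/min.  The calibration slope
default of 2.0 AU/(mg/mL) puts a fully dissolved tablet
(0.222 mg/mL) at ≈ 0.44 AU — the absorbance scale of the reference
standard (intercept 0.4335 AU).  The read-noise default σ = 0.003 AU
makes the replicate-mean standard deviation ≈ 9.5×10⁻⁴ AU, matching the
reference-regression standard error scale (S_y ≈ 9×10⁻⁴, u_m ≈ 1×10⁻⁵)
of the drift-detected scenario.  Weibull defaults τ = 40 min, β = 0.9
give ~93 % release at 120 min.  Outliers are injected as a fixed
absorbance offset added to *every* replicate of a named sampling time: a
contaminated or scattering aliquot corrupts all reads of that cuvette,
so the curve point itself becomes an outlier.

What the simulator does **not** emulate: tablet-to-tablet dose
variability, disintegration lag phases, nonlinear (lamp warm-up) drift,
absorbance nonlinearity at high optical density, and turbidity from
suspended particulates (only its net effect, as additive spikes).
Passing tests therefore demonstrate correctness of the analysis chain
under the stated noise model, not robustness to every bench artifact.

## Drift analysis

Reference replicates are averaged first, so each reference read
contributes one regression point (five half-hourly reads → residual
df = 3).  `linest` reports the complete simple-OLS summary; the slope
t-test uses t = slope/u_m against the two-sided Student-t quantile
(3.182 at 95 %, df = 3).  The F statistic equals t² for a single
predictor — an identity the tests assert.

The correction is **additive**: every replicate at time t becomes
A − m̂·t, anchored at t = 0 where the instrument was blanked.  A linear
background drift is additive in the Beer's-law signal, which is why the
corrected reference series becomes constant at its t = 0 level.
Multiplicative (sensitivity) drift is deliberately not modeled.  The
default policy corrects only when the slope test rejects at α = 0.05;
`always` is available.  The correction is idempotent: refitting the
corrected references gives slope ≈ 0, so a second pass is a no-op.

## Curve building

Per-point uncertainty: the standard error of the replicate mean is
propagated through the calibration and the C∞ normalisation; the small
covariance introduced between points by the cumulative aliquot term is
neglected (the correction itself is ≈ 6 % of signal by 120 min at
5 mL/900 mL and the cross-terms are second-order).

C∞ defaults to the **plateau** mode (mean of the last 3 corrected
concentrations), which normalises to the observed complete-dissolution
level and is invariant to the calibration slope; `label_dose`
(D/V) is offered when the tablet demonstrably dissolves completely.
With the Weibull defaults the 120-min plateau sits at ~93 % of true
release, so plateau normalisation stretches the percent scale by ~7 %;
this rescales K but not the shape of the window, and it is the same
convention a bench analyst uses when normalising to the final reading.

### Outlier screening

Residuals are taken from a centred moving median of window 5.  On a
strictly monotone series the centred median equals the point itself, so
clean curves produce exactly zero residuals wherever the full window
exists; the first and last two points have no full window and are never
flagged.  Each pass applies a two-sided Grubbs test (α = 0.05) to the
residuals of the currently unflagged points and flags at most the single
most extreme one; the trend is then recomputed without flagged points
(so a spike cannot displace its neighbours' medians) and passes repeat
until no rejection.  Flagged points are retained but marked; the fit
window and profile pairing exclude them.  Sensitivity at the default
noise level: spikes ≥ 0.02 AU (~20× the replicate-mean SD) are flagged
reliably with no neighbour false positives; smaller spikes may pass.

## Kinetic fitting

The fit window keeps points with Q ≤ 60 % (inclusive, on the final
percent scale), t > 0, and no outlier flag; fewer than 3 survivors is an
error.  The objective is the unweighted residual sum of squares on the
fraction scale (K rescales by 100 on the percent scale; n is unchanged).

The optimiser is a damped Gauss–Newton (Levenberg–Marquardt) iteration
in (ln K, n) — the log keeps K > 0 without constraints.  Each start runs
until an accepted step improves χ² by less than `chi2_tol`
(default 10⁻¹²) or the damping parameter saturates (no downhill step
within numerical resolution); `max_iter` (default 500) accepted steps is
the non-convergence cut-off.  Starts default to the log-linear OLS
initialisation (exact on noiseless power-law data) plus a 3×3 grid
K₀·{½,1,2} × n₀+{−¼,0,+¼}; the best converged start is reported and the
whole per-start table kept, so a rugged χ² surface is visible in the
output.  Standard errors are Gauss–Markov: cov = s²(JᵀJ)⁻¹ at the
optimum with s² = χ²/(N−2), and K_se = K·se(ln K) by the delta method.

Residual randomness: Wald–Wolfowitz runs test on residual signs
(normal approximation, two-sided; zeros dropped).  When all residuals
are ~0 (noiseless correct-model fits) the test is reported
not-applicable (NaN); all-one-sign residuals are flagged as systematic
misfit.  The normal approximation's size was checked by Monte Carlo at
50 residuals (≈5 % rejection at α = 0.05); at the 6–8 points of a
typical fit window the test is indicative only, and the code warns
below 6 signed residuals.

### Recovery under model mismatch

With Weibull truth the fitted n estimates the best power-law exponent
over the 60 % window, not β (for τ = 40, β = 0.9 the window-averaged
log-slope is ≈ 0.71).  Estimator *bias* is therefore measured against
the same pipeline run on the noiseless, driftless limit of the same
configuration: over 200 noisy bench-protocol runs the mean fitted n
differs from that reference by < 10⁻³, and drift is detected in ~96 %
of runs.

## Profile comparison

f₁ = 100·Σ|R−T|/ΣR (asymmetric: the denominator is the reference sum)
and f₂ = 50·log₁₀(100/√(1+MSD)) (symmetric; exactly 100 for identical
profiles, below 50 once the RMS difference passes ~10 %).  Curves must
share an identical time grid — mismatched grids raise an error rather
than silently interpolating, since resampling changes f₂.  Points
flagged as outliers in either curve are dropped from both.  The default
keeps all shared points; the `fda_85_rule` truncation (keep up to and
including the first point at which both profiles exceed 85 %) is offered
for regulatory-style comparisons.  The consistency decision is strict:
f₁ < 15 AND f₂ > 50.

## Problem sizes and determinism

Monte-Carlo suites use 200–2000 replicates (type-I error and power of
the drift test, runs-test size, Weibull-regime recovery), sizes at which
the binomial sampling error is well inside the asserted bands.  All
randomness flows through `numpy.random.default_rng` seeded from the
configuration, so every artifact — including the JSON reports, written
with sorted keys and repr-faithful CSV numbers — is byte-reproducible
from config + seed.

## Known limitations

- Additive linear drift only; no multiplicative or nonlinear drift.
- Aliquot-correction uncertainty propagation ignores cross-point
  covariance.
- Edge points (first/last two) are exempt from outlier screening.
- The runs test uses the normal approximation, coarse below ~10 points.
- Alternative kinetic models (zero-order, Higuchi, Hixson–Crowell) are
  out of scope; the fitter is specific to the power law.
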