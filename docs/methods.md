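# Methods

This note records the models, procedures and numerical choices behind
`specfe`, in the order data flows through the package.

## Synthetic spectra generator

No public fruit spectra dataset accompanies this kind of SSC study, so the
package validates itself on synthetic data whose *statistical* structure
matches what such studies report, with ground truth planted where the real
analysis has none.

**Signal model.** A clean spectrum is a smooth continuum minus Gaussian
absorption bands:

```
r_i(λ) = c(λ) − Σ_b (d_b + k_b · (z_i + η_i)) · exp(−(λ − μ_b)² / 2w_b²)
```

- `c(λ)` is a logistic ramp rising from low reflectance at 450 nm to a
  plateau near 780 nm, multiplied by a factor that rolls off smoothly to
  `1 − low_wavelength_damping` below 500 nm. Together with the
  multiplicative scatter gain this reproduces the narrow-variance-below-500,
  broad-variance-above-750 pattern of real fruit spectra without claiming
  radiative-transfer realism.
- Bands sit at 600, 680, 840 and 960 nm (widths 18/15/25/20 nm, baseline
  depths 0.05/0.06/0.09/0.07). The 600 nm band has zero SSC coupling (pure
  structure); the other three couple with `k_b = 0.01` per standardized SSC
  unit, so the informative wavelengths concentrate in the 600–700 nm region
  and above 750 nm.
- `z_i` is the sample's standardized SSC; SSC itself is drawn from
  N(13.148, 1.025²) % Brix truncated to positive values by redrawing
  (n = 116 by default, grid 450–1000 nm at 2.5 nm, p = 221).

**Latent chemistry deviation.** `η_i ~ N(0, chem_noise_sd²)` (default 1.0,
in z units) is a per-sample deviation between refractometric SSC and the
chemistry the spectrum actually expresses. It is the package's own design
choice for a genuinely open point: without it, a handful of wavelengths
predicts SSC almost perfectly (RPD ≫ 10), which no Vis-NIR SSC study
reports, and the no-selection baseline *beats* feature selection —
inverting the phenomenon the analysis exists to study. With
`chem_noise_sd = 1`, attainable R² is capped at 1/(1 + 1) = 0.5 (RPD ≈
1.4) no matter how good the pipeline, which is the regime such studies
report; disturbances and model choices then differentiate pipelines below
that ceiling. Because η is shared across bands, extra informative
wavelengths reduce sensor noise but not the chemistry gap, keeping the
optimal feature count small.

**Disturbances.** Each row is transformed as
`gain_i · r_i + offset_i + slope_i · u + ε`, with `u` the wavelength
normalized to [0, 1]: lognormal gain (σ = 0.08; lognormal keeps reflectance
positive), normal drift offset/slope (0.02 / 0.04), i.i.d. noise
(σ = 0.01). These defaults were chosen once so that the untreated baseline
lands below RPD 1 and the best pipelines near the ceiling; they are not
refit to any downstream result. The generator writes a wide CSV
(`sample_id,ssc,<nm>,...`) and a ground-truth JSON sidecar (informative
band centers and nearest grid indices) so selector recovery is testable.

What the generator does *not* emulate: hyperspectral image cubes and the
extraction of per-fruit mean spectra (only 1-D spectra per sample),
wavelength-correlated sensor noise, nonlinear detector effects, and any
tissue-optics realism. Tests passing on this generator therefore show the
pipeline mechanics are correct and that methods behave as designed under
the planted structure — not that any particular accuracy will transfer to
real fruit.

## Pre-processing

- **SNV** standardizes each spectrum to mean 0, SD 1 using the *sample* SD
  (denominator p − 1; fixed so tests are exact). Constant spectra raise a
  named error.
- **Detrend (DC)** fits and subtracts a per-spectrum polynomial in
  wavelength (default degree 1, "trend lines"); implemented via a shared QR
  basis on wavelengths scaled to [−1, 1], so the residual is exactly
  orthogonal to the basis and the transform is idempotent.
- **Savitzky–Golay (SG)** uses `scipy.signal.savgol_filter` (default window
  11, order 2; both configurable since no single convention exists), edges
  by polynomial extrapolation of the boundary fits.
- **DOSC** removes spectral variation orthogonal to the response. Fit:
  center X and y; anti-project X off y (`Z = X_c − y_c(y_cᵀy_c)⁻¹y_cᵀX_c`);
  take the leading principal-component score `t` of Z; loading
  `p = X_dᵀt/tᵀt`; weights as the minimum-norm solution of `X_c w = t` so
  new spectra can be corrected with calibration-fitted parameters; deflate
  and repeat (default n_osc = 1, configurable). Scores are orthogonal to
  y_c by construction; a component is skipped when the leading singular
  value of Z falls below 1e-10 of ‖X_c‖ (nothing orthogonal left to
  remove — the rank-one-aligned-with-y case).

## Feature selection

All nine methods share a fit/apply `Selector`. Ties in ranker scores break
toward the lower wavelength index (determinism). Defaults the field does
not standardize are exposed as configuration: MI uses the k-NN estimator
with k = 3 and a seeded jitter; kernel PCA uses an RBF kernel with inverse
length-scale 1/p (a linear-kernel option exists solely to cross-check
against PCA); RFE standardizes columns once to unit sample variance and
refits OLS after each single-column removal, so the surviving sets are
nested; SPA builds one projection chain per start column (largest residual
norm after orthogonal projection on the chosen span) and scores every
(start, length) candidate, length in [2, min(25, n − 2)], by pooled 5-fold
OLS RMSE; CARS runs 50 Monte-Carlo iterations at an 0.8 sampling ratio with
PLS components chosen by internal 5-fold CV (capped at 10), the exponential
decay schedule `r_i = a·e^(−k·i)` with `r_1 = 1`, `r_N = 2/p`, weighted
resampling of the kept wavelengths, and returns the retained set with
minimal RMSECV. CARS uses PLS only internally; the downstream model is
always OLS, and SPA's candidate scoring also uses OLS for consistency with
that downstream model.

## Evaluation protocol

- **SPXY split** with joint distance `d_x/max d_x + d_y/max d_y`,
  Kennard–Stone max–min selection, calibration size `round(0.75 n)` for the
  3:1 ratio (87/29 at n = 116). Deterministic; degenerate all-identical
  inputs raise.
- **OLS** always includes an intercept and solves by minimum-norm least
  squares, so the q > n no-selection cells are well-defined instead of
  crashing.
- **Metrics**: RMSE; MAPE as a fraction; RPD = sample SD (N − 1) of the
  measured values of the evaluated set divided by RMSE. The N − 1
  convention is a documented choice — the two plausible conventions differ
  by under 1% at these sample sizes and published tables do not pin one
  down. Zero RMSE reports RPD = +inf with a warning.
- **Cross-validation**: seeded shuffled 5-fold on the calibration set.
  DOSC and all selectors are refitted inside each fold (the conservative,
  leakage-free reading of the protocol; a `leaky` flag exists for
  comparison studies and defaults off). For projections, rankers and RFE
  the feature count n minimizing mean fold RMSE over 1..min(30, fold size −
  2) is selected, exploiting nestedness so each fold fits the method once;
  SPA and CARS size their subsets internally per fold, and the reported n
  comes from the full-calibration fit. The calibration triple is the fold
  mean (each fold's RPD uses that fold's SD); the prediction triple comes
  from one full-calibration fit applied once to the prediction set.
- **Grid**: all 5 × 10 recipes share one split and one fold seed; per-cell
  seeds derive from the master seed by stable name hashing so adding a
  method never perturbs the others. Failures are captured per row (NA
  metrics + reason), never raised. The best-frequency tally compares at
  full floating precision (displayed roundings can alias distinct values),
  breaks ties by canonical method order with a warning, and never lets a
  failed row win; each group row therefore sums to 6 (three calibration +
  three prediction metrics).

## Stacking

The two default bases are the detrend+CARS and SG+CARS pipelines (the
classic "best in calibration" / "best in prediction" pair). The meta-model
is OLS with intercept over exactly the two base prediction columns. It is
trained on *out-of-fold* base predictions from a fold partition shared
across bases — the standard remedy for the refitting bias that motivates
stacking; nothing from the prediction set enters the fit. Identical (or
collinear) bases are handled by the minimum-norm meta solution. Base
pipelines are refitted on the full calibration set for deployment.

## Problem sizes and determinism

Default validation sizes are the study scale itself: 116 × 221 datasets,
50-cell grids, 20-replicate comparisons for stochastic claims (planted-band
recovery, SNV vs. none under scatter, stacking vs. its bases). All
randomness — generator, fold shuffles, CARS Monte-Carlo draws, MI jitter —
flows from explicit integer seeds, and every reported number is
reproducible byte-for-byte from those seeds.

## Known limitations

- The generator's band/disturbance family is linear-Gaussian; selectors
  that hunt nonlinearity (MI, kernel PCA) are exercised but not favored by
  the data.
- SPA's candidate search is exhaustive over start columns; for p much
  beyond a few hundred wavelengths it becomes the slowest component.
- DOSC weights use a minimum-norm inverse of the calibration spectra; with
  fewer calibration samples than wavelengths the correction of genuinely
  out-of-distribution spectra is an extrapolation.
- `cv_evaluate` reports SPA/CARS calibration metrics from per-fold internal
  searches whose selected subsets may differ across folds; the fold mean
  then measures the *procedure*, not one fixed wavelength set.
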