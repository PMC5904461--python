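# Methods

This note records the statistical models, the numerical conventions and
the design decisions behind `latreg`, at the level of detail a maintainer
or a careful user needs. Everything stated here is exercised by the test
suite or by `scripts/acceptance.py`; nothing is an empirical claim beyond
what those compute.

## Lattice embedding

Observations are keyed by integer cell coordinates `(x, y)`; `x` maps to
matrix columns, `y` to rows, rows ordered by increasing `y` (an arbitrary
but fixed convention, so correlograms and wavelet components are
reproducible). For wavelet work a variable is embedded into the smallest
dyadic square with side `2^J ≥ ceil(padzone × max(extent_x, extent_y))`;
`padzone > 1` (e.g. 1.1) inserts a guard frame against the periodic
transform's wrap-around. Unobserved cells take the pad fill: zeros, the
mean of the observed values (default), or values mirror-reflected across
the bounding box. Interior holes of non-rectangular data are filled with
the pad value, never interpolated; a log message reports how many. The
embedding is exactly invertible at the observation cells for every
padform and padzone (tested as a round-trip property).

## Moran's I correlograms (`acfft`)

For distance bin `[lo, hi)`,

    I = (n / S0) · Σ_{i≠j} w_ij (f_i − f̄)(f_j − f̄) / Σ_i (f_i − f̄)²,

with `w_ij = 1` when the Euclidean inter-cell distance falls in the bin
(ordered pairs, `S0 = Σ w_ij`). Bin k covers `[lim1 + k·h, lim2 + k·h)`
with `h = lim2 − lim1`; defaults `lim1=0, lim2=1, dmax=10`. The pair sums
for all lag offsets are read off one linear (zero-padded) 2-D FFT
autocorrelation of the value grid and of the observation mask — this is
exact, not an approximation, and is verified bin-by-bin against an O(n²)
pair-enumeration oracle at 1e-10. `f` is centred internally, so the
statistic is invariant to adding a constant; it is also invariant to
coordinate translation. Bins containing no pair return NaN — note that on
a lattice the default first bin `[0, 1)` is always empty because the
minimum inter-cell distance is 1. Lag-1 statistics used in the tests are
therefore computed with an explicit distance-1-only bin (`[0.9, 1.1)`).
Constant input yields an all-NaN profile with a warning.

## GLM engine

IRLS with canonical links only (identity / logit / log), convergence when
the relative coefficient change falls below 1e-8 (≤ 100 iterations; both
configurable). Rank-deficient designs raise an error naming the collinear
columns (QR with pivoting). For the logit and log links, update steps that
would push `|η|` beyond 30 are halved (such means are astronomically
outside any realistic count/probability range), and a fit ending there is
flagged non-converged — this catches complete separation. Pearson
residuals are `(y − μ̂)/√V(μ̂)`, divided by `√φ̂` for the gaussian family
unless the fit is numerically saturated (φ̂ at round-off level), where
that division would manufacture spurious O(1) residuals from round-off.
Dispersion `φ̂ = Σ r²/(n − k)`.

Information criteria: `ℓ` is the exact log likelihood at the fitted means
(gaussian profiles out `σ̂² = MSE`); `AIC = −2ℓ + 2k` with k counting
regression coefficients plus one for the gaussian variance — this
convention must be fixed for model-table deltas to be well defined;
`AICc = AIC + 2k(k+1)/(n−k−1)`, reported as NaN (strict callers: an
error) when `n − k − 1 ≤ 0`.

## Spatial GEE

Fisher scoring on the estimating equation
`Σ D'V⁻¹(y − μ) = 0`, `V = φ A^{1/2} R A^{1/2}`, to relative tolerance
1e-6. Structures:

- **independence** — delegates to the GLM; coefficients and standard
  errors are bit-identical to it.
- **fixed** — `R_ij = a^{d_ij}`. The base `a` is fitted by bounded least
  squares of `a^d` to the GLM residual correlogram, using each bin's left
  edge as its distance label (on a lattice the left edge is the dominant
  and smallest distance inside a unit-width bin; the empty `[0,1)` bin
  drops out). Fallback: the lag-1 value clamped to `[0, 0.99]`. `R` is
  frozen during scoring. Refused for n > 20 000 (the dense matrix
  becomes intractable; the clustered structures are the intended
  fallback).
- **exchangeable / quadratic** — axis-aligned cluster×cluster tiles
  anchored at the grid origin (cluster ∈ {2,3,4}, default 3; partial
  tiles form smaller blocks). Within-block parameters are moment
  estimates from Pearson-residual products (pooled per distinct
  within-tile distance for quadratic), alternated with β updates until
  joint convergence. Estimates are clamped to `[−0.3, 0.99]` and any
  non-positive-definite block is ridged with a warning.

`φ` is 1 when `scale_fix` is set (non-gaussian), else the Pearson moment
estimate. Reported standard errors are model-based `(D'V⁻¹D)⁻¹` — this is
what makes the independence GEE reproduce the GLM exactly — with the
robust sandwich kept on the fit object.

**Sandwich grouping.** The robust covariance is `Ω⁻¹ M Ω⁻¹` with
`M = Σ_g (Σ_{i∈g} d_i u_i)(·)'`, `u = V⁻¹(y − μ)`. The groups g are
single observations under independence (reducing to the standard HC
robust covariance, tested against that oracle) and the correlation blocks
for clustered structures. For `fixed` the whole sample is a single
"cluster", whose sandwich is identically zero at the solution (the score
is solved exactly); the meat is therefore pooled over cluster-size tiles
instead. Without this, QIC's penalty term would vanish for every fixed
fit and backward selection would never remove a term.

**Normalised residuals.** `r* = L⁻¹ r_pearson`, with `L` the (block)
Cholesky factor of the working correlation — residuals "normalised in
terms of correlation". With the true simulation correlation supplied as
working `R`, their lag-1 Moran's I is centred at the white-noise null
(tested by simulation).

**QIC** (Pan's form): `−2 Q(μ̂; I) + 2 tr(Ω̂_I⁻¹ V̂_r)`, where Q is the
independence quasi-likelihood at the model's fitted means, `Ω̂_I` the
model-based coefficient covariance of the independence fit of the same
formula, and `V̂_r` the model's robust covariance. Q is evaluated at unit
dispersion for all families: with a model-specific estimated scale the
gaussian fit term collapses to `−2Q = n − k` for every model and the
criterion stops measuring fit at all. (Under this convention the gaussian
QIC behaves like Mallows' Cp: RSS plus a robust complexity penalty.)

## Wavelet engine

Separable 2-D transforms built on PyWavelets: the decimated DWT with
periodized boundaries and the undecimated, translation-invariant MODWT
(`swt2`); families haar and d4 (the 4-tap Daubechies extremal-phase
filter). Components are returned as reconstructed full-resolution fields
(a multiresolution analysis), so values at observation cells are always
defined; boundary-effect control is delegated entirely to the embedding
pad zone. Two identities hold to numerical precision and are tested for
all four family×transform combinations: telescoping
(`smooth(s) = smooth(s+1) + detail(s+1)`) and perfect reconstruction
(`input = smooth(L) + Σ details`). Haar DWT smooths equal nested 2×2
block means, which is also what `upscale` renders: `scale=0` is the raw
embedded matrix, `scale=s` the smooth component at level s on the full
grid (default padding: mean of the input vector).

`wavelet_varcov` computes per-level variance and covariance from the
**coefficient** sub-bands (periodized DWT, or norm-rescaled SWT for the
MODWT), not from the redundant MRA components: the coefficient transforms
are orthonormal, so per-level variances plus the final smooth partition
the embedded grid's variance exactly (tested at 1e-10 on fully observed
dyadic squares); the redundant components satisfy no such identity. Means
are taken over all cells of the embedded frame; on non-dyadic data the
pad frame dilutes all levels by a common factor. The d4/MODWT pairing is
the default as the numerically best-behaved choice for this purpose.

## Wavelet-revised models

Modified IRLS: at each iteration the working response
`z = η + (y − μ) g′(μ)` and every non-constant design column are passed
through the level-L high-pass filter before the weighted solve; weights
come from the current original-scale μ. Convergence at relative change
1e-6, ≤ 200 iterations.

**Intercept and level.** A constant column is pure smooth and would vanish
under the filter, so the intercept column is left unfiltered. The filter
applied to the working response and covariates retains each vector's
grand mean (it removes the smooth components *except* the overall level).
Consequently the intercept absorbs the data's level, fitted values
`μ̂ = g⁻¹(Xβ̂)` live on the original scale (so `predict` and `aic_calc`
behave as for a GLM), and the slopes are driven purely by the detail
components — a pure high-pass would zero the working response's mean,
collapse the intercept and send the Poisson iteration off-level.

**Residuals.** `resid_raw` is `y − μ̂` on the original scale. The
Pearson-type residuals (and the residual autocorrelation profile) are the
weighted working residuals on the *filtered* scale,
`r = √W (z_f − X_f β̂)`: this is the quantity the filter actually
decorrelates. The original-scale residuals necessarily retain whatever
smooth field the model deliberately treats as nuisance. Note an intrinsic
property of any level-1 high-pass: it is (close to) a projection that
removes the rank-n/4 smooth subspace, so even white-noise residuals
acquire a lag-1 Moran's I around −1/6 (haar; d4 similar). The meaningful
statement — WRM residual |I(1)| well below the uncorrected GLM's — holds
essentially always on confounded fixtures and is what the tests assert; a
bound of |I(1)| < 0.1 is not attainable for level-1 filtering, by this
structural argument rather than any estimation failure.

Standard errors are naive `(X_f'WX_f)⁻¹φ` on the filtered quantities
(`φ = 1` for counts/occurrence unless scale estimation is requested);
p-values use the normal reference. Defaults: haar, dwt, level 1, mean
padding, padzone 1.

`scale_wmrr` replaces the high-pass with the single-scale detail (or
smooth) component; detail components get the grand mean restored exactly
as above, smooth components already carry it. With details at scale 1 it
is algebraically identical to the WRM at level 1 (there is nothing to
decompose below the finest scale) — tested to 1e-8. Regressing smooths at
full depth on a fully observed dyadic square degenerates (every smooth is
the constant grand-mean field) and raises the collinearity error.

## Model selection

Criteria: QIC for GEEs, AIC (or AICc on request) for WRM/WMRR.
`step_backward` does backward selection only: at each step all single-term
deletions that respect the hierarchy are refitted, the lowest-criterion
deletion is taken if it strictly improves the current criterion, ties
among deletions break by term label order. Hierarchy is syntactic: a term
blocks the removal of any lower-degree term whose symbols it contains
(`x` stays while `I(x^2)` or `x:y` remains). `mmi` enumerates all `2^p`
subsets (p ≤ 12 guard), always keeping the intercept; failed subset fits
are flagged and excluded from the weight normalisation; tables sort by
criterion, then fewer terms, then lexical labels. Akaike weights are
`exp(−Δ/2)` normalised. `rvi` runs `mmi` on `scale_wmrr` fits for each
scale 1..maxlevel; RVI(variable, scale) is the summed weight of models
containing the variable. Forward selection is deliberately not
implemented.

## Accuracy measures

`smooth_actuals` replaces each binary actual by the mean over its 3×3
queen neighbourhood (observed cells only; window size configurable).

`th_dep` (threshold-dependent): with `spatial=False`, the classical 2×2
confusion matrix at threshold t, Cohen's kappa, sensitivity, specificity —
verified to 1e-10 against independently coded textbook formulas. With
`spatial=True`, both the smoothed actuals and the *smoothed* predictions
are mapped into 4 ordinal classes by the cut points
`{t/2, t, (1+t)/2}` (half-open upward, class 4 closed at 1) and the 4×4
table is scored with weighted kappa, weights `w_ij = 1 − |i−j|/3`
(`κ_w = (p_o(w) − p_e(w))/(1 − p_e(w))`). Smoothing both sides is what
makes κ = 1 for predictions identical to the actuals — comparing raw
predictions against smoothed actuals can never agree perfectly at patch
edges. Sensitivity/specificity come from collapsing classes {3,4} to
"positive". The 4-class construction, the linear weight pattern and the
queen smoothing are this package's documented instantiation of the
weighted-table idea, constrained to (a) reduce to the classical metrics
when `spatial=False`, (b) give partial credit to near misses, (c) score
perfect agreement as κ = 1.

`th_indep` (threshold-independent): thresholds sweep the midpoints
between consecutive distinct predicted probabilities, so ties share a
threshold and the classical (`spatial=False`) curve integrates to exactly
the Mann–Whitney AUC (tested at 1e-10). With `spatial=True` each
predicted-positive cell contributes its neighbourhood presence fraction
`a*` to the true positives and `1 − a*` to the false positives
(symmetrically for predicted negatives); AUC by trapezoid,
`TSS = max(sens + spec − 1)`. Because mean-smoothing conserves presence
mass, the soft curve has an intrinsic ceiling below 1; spatial scores
exceed classical ones exactly when displacement has destroyed the crisp
cell-wise overlap while staying within the queen neighbourhood — the
near-miss regime these measures exist for.

## Synthetic data

Spatial structure comes from Gaussian-kernel smoothing of white noise on
a torus (`ac_range` = kernel sd in cells); fields are standardised. This
is cheap, fully seeded, and produces the monotone autocorrelation the
tests require, but it is not a parametric covariance model: variogram
shapes, anisotropy, non-stationarity and irregular survey footprints of
real data are not emulated, so passing tests demonstrate correctness of
the estimators under these controlled conditions, not field performance.

`make_musdata_like` / `make_carlinadata_like`: full `grid_side²` lattice
(default 24), Poisson response with
`η = β₀ + β₁x₁ + β₂x₂ + c`, default β = (0.5, 0.3, −0.4). The two
covariates are smoothed fields (range `ac_range`, default 3); the
confounder c re-uses the covariate source noise smoothed at twice the
range plus an independent smooth component, scaled to
`confounder_strength` (default 1). Sharing sources is deliberate: it
correlates c with the covariates' low-frequency parts, which is what
biases naive GLM slopes and gives the spatial models something to
correct. With `confounder_strength=0` the GLM recovers the truth
(calibration test).

`make_hook_like`: presence/absence actuals threshold a compact-patch
field (`patch_scale`, default 0.5 — patches of one to a few cells) at the
`1 − prevalence` quantile (default 0.3; calibration exact by
construction). Predictions are a logistic transform of the same field
rolled by `shift_cells` along *both* axes plus noise. The diagonal
one-cell displacement with compact patches is the designed near-miss
regime: predictions stay inside the queen neighbourhood of the true
patches (spatial credit) while the crisp cell-wise overlap collapses
(classical scores fall). With large `patch_scale` and no shift, spatial
and classical AUC agree closely.

## Problem sizes and numerical details

The simulation-based tests use 24×24 lattices with 100 seeded replicates
for the confounding sweep, 16×16 frames for wavelet identities, 50 seeds
for the FFT/brute-force equivalence, 500 randomized formulas for the
hierarchy property, and 20 seeds for the near-miss property; the
acceptance script uses 30-replicate sweeps. These sizes give stable Monte
Carlo summaries (3-SE bands where distributions are checked) at a few
minutes of total runtime. Ties at bin boundaries are resolved by
half-open intervals throughout; correlation matrices are ridged to
positive definiteness only on Cholesky failure, with a warning; all
generators and tests derive their randomness from explicit seeds.

## Known limitations

- Canonical links only; no offsets, weights, negative binomial, or
  user-supplied correlation matrices (beyond the frozen `working_R` hook).
- `corstr="fixed"` is dense: O(n²) memory, refused above 20 000 cells.
- Wavelet families are limited to haar and d4; levels are integers, and
  dyadic embedding means up to three quarters of the frame can be padding
  for awkward extents.
- The MODWT-filtered WRM can fail to converge on strongly confounded
  count data (flagged, never silent); the haar/DWT default is the robust
  path.
- Accuracy measures assume binary actuals and probabilities in [0, 1];
  prevalence-stratified variants are out of scope.
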