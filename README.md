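# latreg — spatial regression and model evaluation for lattice data

Grid-based data — species counts or occurrences per raster cell, pollutant
concentrations, socio-economic indices — are usually spatially dependent:
nearby cells hold similar values. Standard GLMs then understate standard
errors, inflate type-I error rates, and, when an unobserved smooth field is
correlated with the covariates, bias the slope estimates themselves.
`latreg` is a toolkit for regression and model evaluation on such
two-dimensional lattice data, aimed at ecologists and epidemiologists
modelling species distributions or abundance on grids, and at anyone else
fitting GLM-type models to raster data.

## What it implements

**Spatial GEEs** (`fit_gee`). Generalised estimating equations replace the
independence variance of a GLM with a working variance–covariance matrix
`V = φ A^{1/2} R A^{1/2}`. Supported working correlation structures:

- `independence` — identical to the GLM;
- `fixed` — an isotropic power function `R_ij = a^{d_ij}` with `a` adapted
  once to the Moran's I correlogram of the GLM's Pearson residuals and then
  frozen;
- `exchangeable` / `quadratic` — block-diagonal `R` over cluster×cluster
  tiles of the grid, with within-block parameters moment-estimated (all
  equal, or equal at equal distance).

GEE fits report correlation-normalised Pearson residuals `r* = L⁻¹ r`
(`L` the Cholesky factor of the working correlation) and a QIC score
(Pan's `−2Q + 2 tr(Ω̂⁻¹ V̂_r)`) in place of AIC.

**Wavelet-revised models** (`fit_wrm`). A WRM is a single GLM in which the
response and all explanatory variables are wavelet high-pass filtered —
their smooth (low-frequency) components at a chosen `level` removed —
inside every IRLS iteration, before the coefficients are computed. Because
spatial autocorrelation lives in the smooth components, filtering removes
it; `level=1` filters hardest and usually works best. `scale_wmrr` is the
scale-specific variant (wavelet multiresolution regression): it regresses
on the detail (or smooth) component of a single scale, for scale-dependent
inference; at `scale=1` with details it coincides with the WRM at
`level=1`.

**Supporting machinery.**

- `acfft` — binned Moran's I correlograms computed exactly via 2-D FFT
  cross-correlation (with `moran_bruteforce` as the pair-enumeration
  reference);
- `embed` / `extract` / `upscale` — embedding of scattered lattice
  observations into padded dyadic `2^J × 2^J` squares (zero / mean /
  mirror padding), and rendering of smooth components at coarser dyadic
  resolutions;
- `wavelet_varcov` — wavelet variance and covariance by scale (d4/MODWT by
  default);
- `step_backward`, `mmi`, `rvi` — backward stepwise selection (respecting
  term hierarchy), all-subsets multimodel inference with Akaike weights
  (QIC for GEEs, AIC/AICc for WRMs), and relative variable importance as a
  function of wavelet scale;
- `th_dep`, `th_indep` — classical and spatially corrected accuracy
  measures for presence/absence predictions: weighted 4×4 kappa built on
  queen-neighbourhood-smoothed fields, and a soft ROC giving AUC and
  maximum TSS where a predicted presence one cell off an observed presence
  earns partial credit;
- `make_musdata_like`, `make_carlinadata_like`, `make_hook_like` — seeded
  synthetic generators with known ground truth, emulating autocorrelated
  count data with a smooth confounder and near-miss prediction maps.

## Worked example

```python
import latreg as lr

ds = lr.make_musdata_like(lr.SimConfig(seed=1))   # truth: β = (0.5, 0.3, −0.4)
gee = lr.fit_gee(ds.data, "musculus ~ pollution + exposure",
                 "poisson", corstr="fixed")
print(lr.summary_gee(gee, print_autocor_pars=True))
```

```
Spatial GEE, family = poisson, corstr = fixed
Formula: musculus ~ pollution + exposure

              estimate  std_error         z      p_value
(Intercept)   0.898384   0.156795   5.72969  1.00615e-08
pollution     0.524963   0.112451   4.66839  3.03573e-06
exposure     0.0656623   0.114663  0.572654     0.566879

QIC: 192.4055   dispersion: 1.9348
Autocorrelation parameter: a = 0.5898 (R_ij = a^d_ij)

Residual Moran's I (GLM vs GEE), first bins:
  GLM: nan, 0.456, 0.354, 0.268, 0.185
  GEE: nan, -0.098, 0.042, 0.040, 0.012
```

The generator plants slopes 0.3 (pollution) and −0.4 (exposure) plus a
smooth confounding field. The plain GLM on these data estimates 0.67 and
+0.27 — the confounder masquerades as covariate effect and its residual
Moran's I starts at 0.46. The GEE shrinks both the slope bias and the
residual autocorrelation (first bins near zero after normalisation); the
distance-1 correlation of the fitted power structure is `a ≈ 0.59`. A
wavelet-revised fit of the same data (`lr.fit_wrm(..., level=1)`)
estimates 0.65 / −0.22 and reports AIC/AICc instead of QIC. The `nan`
first bin is the default binning's `[0, 1)` bin, which contains no pair of
distinct cells.

The same analyses run from the shell:

```bash
latreg simulate --kind musdata --seed 1 --out mus.csv
latreg gee --input mus.csv --formula "musculus ~ pollution + exposure" \
       --family poisson --corstr fixed --out gee.json --ac-out ac.csv
latreg wrm --input mus.csv --formula "musculus ~ pollution + exposure" \
       --family poisson --level 1 --out wrm.json
latreg accuracy --input hook.csv --spatial --out metrics.json
```

(`latreg --help` lists all subcommands: simulate, glm, gee, wrm, wmrr,
step, mmi, rvi, accuracy, acf, upscale, covar.)

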