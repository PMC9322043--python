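# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `ovaspec`. It states no result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

Egg-white ovalbumin converts irreversibly into thermostable S-ovalbumin
during storage; the S-ovalbumin fraction (percent of total ovalbumin) is a
freshness index. The package calibrates regression models that predict this
percentage from the mean visible/NIR transmittance spectrum of an intact
egg, and transfers the fitted model to every pixel of the hypercube to map
the within-egg content distribution.

## Processing chain

1. **Calibration to transmittance.** `I_c = (I_o − I_d)/(I_w − I_d)`
   voxelwise, with raw cube `I_o`, white reference `I_w` (~full
   transmission) and dark reference `I_d` (shutter closed). Voxels with
   `|I_w − I_d| < eps` (default `1e-6`) carry no information; they are set
   to 0 and counted in the log rather than propagating non-finite values.
2. **ROI segmentation.** The single band nearest 700.4 nm (a
   high-transmission wavelength for egg tissue) is thresholded at
   transmittance `> 0.1` (strict inequality, so an all-background image is
   unambiguously empty). Nearest-band lookup, no interpolation; no
   morphological cleanup by default (hole filling is available behind a
   flag).
3. **Mean spectrum and crop.** The per-band arithmetic mean over ROI pixels
   forms the sample spectrum; bands below 435 nm (low SNR) are dropped,
   leaving 449 of 478 bands. Crop and mean commute for a per-band mean; the
   implementation crops last.
4. **SNV.** Each spectrum is centered and scaled by its own sample standard
   deviation (N−1 denominator), removing per-sample multiplicative scatter
   and additive offsets. Constant spectra are rejected; "constant" is
   judged at float-roundoff scale (`sd ≤ 1e-12·max(1, |mean|)`).
5. **SPXY split.** Pairwise distance = Euclidean spectral distance plus
   absolute response difference, each normalized by its maximum over all
   pairs. The calibration set is seeded with the maximally distant pair and
   grown by the max–min rule to `round(2n/3)` samples (120/60 at n = 180).
   Deterministic; ties break toward the lowest index. The split is run on
   SNV-corrected spectra (the modeling input); a switch allows raw spectra.

## Calibration models

**PLSR (NIPALS, single response).** Per latent variable on centered data:
`w = Xᵀy` (normalized), score `s = Xw`, loadings `p = Xᵀs/sᵀs`,
`q = yᵀs/sᵀs`, then rank-one deflation of X and y. Coefficients
`b = W(PᵀW)⁻¹q`; this orientation is the one that reproduces ordinary least
squares at full rank, which the tests verify against an independent OLS
solve and against scikit-learn's NIPALS implementation (cross-check only —
the implementation is self-contained). Truncating the fitted factor
sequence reproduces smaller models exactly, which makes the per-LV RMSECV
curve computable from one fit per fold.

The LV count is the smallest h whose RMSECV is within 2% of the curve
minimum (plateau rule: past the elbow further LVs buy nothing but variance).
The RMSECV curve is averaged over 5 seeded fold reshuffles before applying
the rule; a single 5-fold split leaves enough noise in the curve to
occasionally inflate h by 2, and the selected h should be stable across CV
seeds.

**LSSVM (RBF kernel).** Equality-constrained SVM regression; training
solves one (n+1)-dimensional KKT system
`[[0, 1ᵀ], [1, K + I/γ]]·[b; α] = [0; y]` with
`K_ij = exp(−‖x_i−x_j‖²/2σ²)`. The response is standardized internally
(centered, unit variance) so the γ grid has a data-independent effective
range; predictions are returned on the original scale. The max-norm KKT
residual is stored on every fit and asserted < 1e−8 in the tests.
Hyperparameters (γ, 1/σ²) minimize five-fold RMSECV over a two-stage
log₂-space grid: unit steps on [−8, 8]² (17×17 = 289 evaluations), then
0.1 steps on ±1 around the coarse optimum. The pairwise squared distances
are computed once and shared across all candidate pairs.

**Metrics.** `RMSE = √(Σ(ŷ−y)²/n)` (n denominator) and `R² = 1 − SSE/SST`,
computed once on pooled out-of-fold predictions for CV metrics. Fold
assignment is a seeded uniform shuffle with near-equal fold sizes.

## CARS wavelength selection

For runs i = 1…N (default N = 100) on the currently retained variable set:

1. Fit PLS on a Monte-Carlo draw of 80% of the calibration samples
   (without replacement), with the LV count chosen by internal five-fold CV
   capped at `min(10, n_retained, n_mc − 1)`; weight each variable by its
   absolute regression coefficient.
2. EDF: force the retained count down the schedule
   `r_i = a·e^(−k·i)`, `a = (p/2)^(1/(N−1))`, `k = ln(p/2)/(N−1)`, so
   `r_1 = 1` and the final count is 2; keep the top-weight variables
   (stable sort, lowest index on ties), never letting the count rise.
3. ARS: draw p times (p = total variable count, as in the original method)
   with replacement among the EDF survivors with probability `|b_j|/Σ|b|`;
   variables drawn at least once survive. Zero-weight variables have zero
   selection probability. Should the set collapse below 2 variables the run
   loop stops early and the traces are truncated.
4. Refit PLS on the survivors with all calibration samples and record its
   five-fold RMSECV, minimized over the LV count.

The subset recorded at the run with minimum RMSECV wins. Two design points
matter for honesty of the argmin: the recorded RMSECV uses the *same* three
seeded CV partitions (averaged) for every run, because a per-run partition
would let the winner be selected for split luck as much as subset quality;
and the drawn-at-least-once rule means early runs with diffuse weights thin
gradually (~63% survive a saturated draw) while concentrated informative
subsets survive intact — producing the characteristic fast-then-refined
two-phase decay of the retained-count trace.

## Pixel-wise chemical maps

Each ROI pixel's spectrum is cropped to the effective range, SNV-scaled
over the **full** 449-band range, then subset to the model's feature
wavelengths and predicted. SNV must see the full range: a model calibrated
on full-range SNV spectra is meaningless on spectra standardized over a
different band set (a practical consequence: a future filter-based
multispectral instrument would need either full-range coverage for the
standardization or a recalibrated model). Predictions are clipped to
[0, 100]% — the assay is a ratio of absorbances and cannot leave that
range. Degenerate (constant) pixel spectra become NaN and are logged.
Maps are rendered with a linear color bar over a shared [0, 100]% range so
eggs from different storage days are directly comparable (blue = low,
red = high; background neutral gray).

## Synthetic-data generator

The generator emulates the study conditions so the full pipeline is
testable without measured cubes; all outputs are pure functions of
(design, seed), with one spawned RNG stream per egg so streaming and batch
generation agree.

- **Design:** 18 eggs per storage day at days 0, 3, …, 27 (180 eggs);
  64×64×478 cubes by default (desk-scale spatial resolution).
- **Wavelength grid:** 29 bands linearly spaced on [401, 434.5] nm plus
  449 on [435, 1002] nm. The real instrument grid is unknown; this
  piecewise construction makes the 478 → 449 crop count exact by design.
- **Storage trend:** expected content fraction
  `f(day) = 0.11 + 0.84/(1 + e^(−0.25(day−12)))` — a logistic stand-in
  rising from ~0.15 to ~0.93, since only the monotone trend and the
  observed ~11–94% range are claimed for the real data. Per-egg content =
  `f(day)` + Gaussian jitter (sd 0.04), clipped to [0.10, 0.95].
- **Spectra:** `T(λ) = gain·B(λ)·exp(−[a0(λ) + c·a1(λ)]) + offset + ε`,
  with a smooth baseline B peaking in the red/NIR; fixed absorption lobes
  at 589, 643 nm (shell pigment) and 750, 970 nm (water O–H overtones);
  content-dependent lobes at 700, 740, 870, 960 nm plus a broad term, all
  non-negative so mean transmittance strictly decreases with content.
  Per-egg scatter gain is lognormal (sd 0.15 in log) and the offset
  Gaussian (sd 0.01) — exactly the distortion family SNV removes.
  Band noise ε has sd 0.004 (transmittance units), inflated 6× below
  435 nm to emulate the low-SNR region that motivates the crop.
- **Within-egg heterogeneity:** a Gaussian random field smoothed with a
  3-pixel kernel (sd 0.03 in content fraction) added to the egg content
  per ROI pixel, so chemical maps are visibly uneven while the ROI mean
  stays near the egg value.
- **Camera model:** white level ~3800 counts with mild vignetting and a
  smooth lamp spectrum, dark level 100 counts, additive sensor noise;
  raw = dark + T·(white − dark) + noise. Background transmittance ~0.005.
- **Reference assay:** `100·O_heated/O_unheated` with lognormal `O_unheated`
  and multiplicative Gaussian error (cv 0.03, configurable — the real
  assay's error is not documented) on the heated reading, clipped to
  [0, 100]. The reference draw precedes all shape-dependent draws, so the
  ground-truth table is invariant to the rendered cube size.

**What the generator does not emulate — and what that implies.** Spectral
noise is pixel-iid, so averaging over ~1–3 thousand ROI pixels makes the
mean spectra nearly noiseless, and every effective band is a clean smooth
function of content. Consequently (i) model errors on synthetic data sit at
the reference-assay noise floor (RMSEP ~1–2 points, far below the ~7–9
points reported for real eggs), and (ii) wavelength selection cannot
*improve* a full-spectrum model the way it does on real spectra with noisy
or uninformative regions — the kernel model keeps its accuracy on the
selected subset, while the linear model pays a small winner's-curse premium
(a few percent relative) for the subset refit. Passing tests therefore
demonstrate correctness of the algorithms and recovery of planted structure,
not field performance. There is no radiometric camera model, no
eggshell-thickness or yolk optics, and one egg per frame.

## Problem sizes used

Unit tests run on 20-egg, 24×24-cube datasets and small random matrices;
the end-to-end checks and the acceptance script run the full default study
(180 eggs, 64×64×478 cubes), which completes in well under a minute on one
CPU. CARS planted-recovery checks use 200×60 designs over 20 seeds.

## Degenerate inputs and tie-breaks

- Calibration: degenerate denominators → 0 with a logged count.
- Segmentation: empty mask → `RoiNotFoundError`.
- SNV: constant spectrum → `ValueError` (roundoff-scale sd counts as
  constant).
- SPXY: all-identical samples → warning, index-order tie-break; argmax ties
  resolve to the lowest index.
- PLSR: h outside [1, min(n−1, p)] → `ValueError`; zero-variance deflation
  residual → rank-deficiency error naming the offending component.
- LSSVM: singular KKT system → error suggesting a larger ridge (smaller γ);
  n = 1 degenerates to predicting the single training value.
- CARS: all-zero weights in a run → keep the EDF cut; collapse below 2
  variables → stop early, truncate traces.
- Grid search: ties resolve to the first-visited grid point (row-major,
  low log₂γ first).
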