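# Methods

This note documents the models, conventions and numerical choices
behind `dceradiomics`: a pipeline that predicts breast-cancer estrogen
(ER) and progesterone (PR) receptor status from multiregional radiomic
signatures on semi-quantitative DCE-MRI kinetic maps.

## Imaging model and kinetic maps

A study is one representative 2-D slice imaged nine times: a
pre-contrast frame SI_0 and eight post-contrast frames SI_1..SI_8.
Subtraction images (SI_t − SI_0, negatives retained) drive lesion
segmentation. Six kinetic maps are computed per pixel:

| map | definition | units |
|---|---|---|
| MSI | max_i (SI_{i+1} − SI_i), i = 0..7 | intensity |
| SI_slope | 100·(SI_8 − SI_mean)/SI_mean, SI_mean = (SI_1+SI_2)/2 | % |
| E_initial | 100·(SI_1 − SI_0)/SI_0 | % |
| ESER | 100·(SI_1 − SI_0)/(SI_2 − SI_0) | % |
| E_peak | 100·(SI_peak − SI_0)/SI_0 | % |
| SEP | 100·(SI_2 − SI_0)/SI_0 | % |

Conventions worth spelling out:

* **MSI index range** includes the pre→first post step (i = 0).
* **Peak timepoint.** "The time-intensity curve" is read as the
  region-mean curve: one peak timepoint per region, applied to every
  pixel. A per-pixel argmax mode exists behind `per_pixel_peak=True`;
  the lesion-level reading is the default because a single curve per
  lesion is the standard clinical object.
* **Degenerate denominators** (SI_0 = 0, SI_2 = SI_0, SI_mean = 0)
  yield map value 0 and set a flag raster. Flagged pixels stay inside
  the ROI so that region size is identical across the six maps.
* Maps are computed once per region, so each region's peak timepoint
  is internally consistent between E_peak and the other maps.

## Segmentation

The intratumoral ROI is obtained semi-automatically: the user (or the
synthetic generator) supplies a rectangular seed box; the subtraction
timepoint with maximum mean enhancement in the box is thresholded by
maximum between-class variance (Otsu, 256 bins, ties toward the lower
threshold with a 1e-9 relative tolerance so histogram-gap plateaus
resolve deterministically); the largest 8-connected supra-threshold
component is kept and holes are filled. The peritumoral ROI is the
ring obtained by dilating the core with a Euclidean disk of
`round(radius_mm / pixel_spacing_mm)` pixels (4 mm at 340 mm / 1024 px
= 0.332 mm/px → 12 px), minus the core, clipped to the breast mask.
Euclidean (not geodesic) distance is used near concavities.

## Feature bank (4980 per case)

Each (region, map) pair — 2 regions × 6 maps — is normalized between
μ ± 3σ of the in-ROI intensities, quantized to 256 gray levels
(round half up; a zero-variance ROI maps to mid-level 128 and is
flagged), and yields 415 features:

* **first-order (15)** on quantized levels: mean, median, min, max,
  range, SD, variance (sample, n−1), skewness and kurtosis
  (population moment ratios m3/m2^1.5 and m4/m2², 0 for a degenerate
  m2), energy, entropy (base 2), uniformity, RMS, mean absolute
  deviation, IQR;
* **GLCM (60)**: symmetric normalized co-occurrence at distance 1 in
  four directions (0°, 45°, 90°, 135°), pairs restricted to the ROI;
  15 Haralick descriptors per direction, not direction-averaged. A
  direction with no valid pair contributes zeros. Logs are base 2;
  difference variance is the variance of p_{x−y} about its mean;
  correlation of a constant ROI is defined as 1;
* **Laws (100)**: all 25 5×5 masks from {L5, E5, S5, W5, R5};
  convolution (reflect padding) of the ROI-z-normalized map;
  texture-energy image = |response| smoothed by a 15×15 mean filter;
  mean/SD/skewness/kurtosis in the ROI;
* **Gabor (240)**: DC-corrected complex kernels, wavelengths
  {2,4,6,8,10} px × 8 orientations (22.5° steps, bandwidth 1 octave);
  ROI magnitude summarized by mean, SD, skewness, kurtosis, energy
  (mean squared magnitude) and a 64-bin histogram entropy.

Laws and Gabor operate on the continuous z-normalized map rather than
the 8-bit levels because filter banks on quantized data alias; for a
zero-variance ROI the raw map is used unscaled (flagged), which keeps
the response of the only non-zero-sum mask (L5L5) physically
meaningful on constant inputs. The 15/60/100/240 family split is this
package's convention, chosen to give the canonical total of
415 × 12 = 4980 named features; any family can be swapped behind the
same interface.

Features are z-standardized column-wise with mean/SD computed on
training rows only (zero-SD columns are set to 0 and recorded). The
reduction runs on a C-contiguous array so results do not depend on the
data frame's internal block layout.

## Signature selection

Patients are split 4:1 by acquisition order (temporal, not random;
floor(0.8·n) earliest patients train). Selection per endpoint and
region:

1. **ICC filter**: two-way random-effects, absolute-agreement,
   single-rater ICC(2,1) between two readers' feature tables
   (vectorized ANOVA mean squares); keep ICC > 0.8 strictly.
   Zero-variance features are undefined and dropped.
2. **Welch t-test**: keep p < 0.1 (pooled-variance mode available).
3. **LASSO**: L1 logistic path, λ geometric from λ_max (the smallest
   all-zero λ) over 25 points down to λ_max/100; λ minimizes 10-fold
   stratified cross-validated binomial deviance (1-SE rule optional);
   folds seeded; fold count capped at the minority-class size on
   small cohorts. Implemented with liblinear (C = 1/(nλ)).
4. **Backward stepwise** under AIC = 2k − 2·logL: repeatedly drop the
   feature whose removal most decreases AIC; stop at a local minimum;
   AIC ties are broken by dropping the largest Wald p-value.

Survivors are strictly nested across stages. The rad-score is the
linear predictor of an unpenalized logistic fit on the survivors;
perfect separation falls back to a weakly ridge-penalized fit and is
flagged. The multiregional signature re-runs LASSO + stepwise on the
deduplicated union of the intra- and peritumoral survivors. If LASSO
shrinks everything to zero the signature degenerates to an
intercept-only model (constant rad-score, AUC 0.5) rather than
aborting; an empty post-t-test candidate set is a hard error. All
statistics — ICC, t-tests, folds, stepwise, standardization moments,
coefficients — are computed from training rows only.

## Evaluation

AUC is the Mann–Whitney concordance (ties half); 95% CIs use DeLong's
placement-value variance, falling back to a seeded stratified
bootstrap (2000 reps) when the variance degenerates (constant
scores). Operating points maximize Youden's J on the training cohort
and are applied fixed to the validation cohort (per-cohort
re-optimization available, since reported sensitivities/specificities
in this literature are often per-cohort). The report is the
2 endpoints × 3 scopes × 2 cohorts grid with ROC overlays and
rad-score distribution plots.

## Synthetic data

No patient cohort is distributed, so two seeded generators define the
test bed; both are pure functions of (config, seed).

**Image-level generator.** An elliptical lesion (semi-axes 10–18 px
at 0.332 mm/px, i.e. ~7–12 mm diameters) inside an elliptical breast
mask on a 128×128 crop. Every lesion pixel follows the empirical
enhancement curve SI(t) = SI_0·[1 + A(1 − e^{−αt})e^{−βt}] — the
minimal wash-in/plateau/wash-out form that all six maps can
distinguish; pharmacokinetic (Tofts) modelling is deliberately
avoided as the analysis is semi-quantitative. Receptor-positive
lesions default to faster, stronger uptake (A = 2.2, α = 1.4/frame,
β = 0.05/frame) than negative ones (1.6, 0.7, 0.12), with
between-patient jitter. The rim (4 mm) and parenchyma follow a fixed
class-independent background curve; only the rim's amplitude is
class-modulated, by 1 + `peritumoral_effect` (default 0.3) in
positive patients — so with `peritumoral_effect = 0` the rim carries
no class information beyond noise, which is asserted as a property.
A correlated Gaussian texture field (correlation 4 px, amplitude
0.15) modulates enhancement; additive Gaussian noise (SD 2 on a
baseline of 100) emulates acquisition noise. ER and PR labels are
drawn jointly with marginal 0.66 (the positive prevalence of the
motivating cohort) and odds ratio 6 via the Plackett construction.
A second reader is simulated by thresholding the mask's signed
distance field at a smooth random offset bounded by `jitter_px`
(default 2); no published inter-reader noise model exists for this
setting, so the jitter magnitude is a free parameter.

**Feature-level cohort simulator.** The selection cascade is a
statistical procedure on a patients × features table, and testing its
operating characteristics needs hundreds of cohorts — far more than
image-level extraction is meant for. `simulate_feature_cohort`
generates that table directly with the structure the pipeline
assumes: intra- and peritumoral feature blocks (80 + 80), four
informative features per region and endpoint (mean shift 0.7
within-class SD), heterogeneous feature scales, a second-reader
replicate in which a random 20% of features carry reader noise large
enough to fail the ICC filter (SD 1.5 vs 0.15), and jointly sampled
ER/PR labels as above, n = 300 by default. Null and recovery suites
(label permutation; multiregional ≥ regional signatures) run on this
simulator. What passing these tests shows is that the *selection and
evaluation machinery* behaves correctly under the assumed feature
statistics; it does not show that real DCE-MRI features follow those
statistics, nor that the image-level generator's textures match real
lesions — real-data performance claims are out of scope.

## Problem sizes used in the shipped checks

Unit and property tests run on 48–64 px studies and cohorts of 8–150;
the end-to-end feature-count check uses one default 128 px case; null
behavior uses 20 permuted feature-level cohorts and recovery 10
planted-signal cohorts at n = 300. The acceptance script re-derives
the per-case feature count, the worked-curve map values, segmentation
Dice over 8 cases, and the full two-endpoint signature pipeline on
one default cohort.

## Known limitations

* Single-slice 2-D analysis only; no volumetric features.
* The per-family feature inventory is a package convention; only the
  4980 total and the four family kinds are externally fixed.
* The synthetic enhancement model has no B1/T1 effects, no k-space or
  motion artifacts, and elliptical geometry only.
* Stepwise selection under AIC is greedy; it is not guaranteed to
  find the global AIC optimum.
* DeLong CIs are asymptotic; very small validation sets get wide and
  approximate intervals.
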