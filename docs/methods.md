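# Methods

## Problem and model

`strokerad` implements a CT-radiomics pipeline for classifying time from
stroke onset (TFS) in M1 middle-cerebral-artery occlusion into the
intravenous-thrombolysis window (early, ≤ 4.5 h, coded 1) versus beyond it
(late, > 4.5 h, coded 0). The pipeline is:

1. **Preprocessing.** The HU volume and its MCA-territory VOI mask are
   resampled to 1 mm isotropic (trilinear image, nearest-neighbour mask),
   in-mask intensities are clipped to a fixed brain window [0, 80] HU and
   mapped to [0, 1], and discretized to 64 equal-width gray levels
   (`level = min(64, floor(v·64) + 1)`). Fixed bins over a fixed window keep
   levels comparable across subjects; both are configurable.
2. **Feature extraction.** 396 features per subject: 42 first-order
   (21 summary statistics + 21 nearest-rank percentiles, where percentile p
   is the ⌈p/100·n⌉-th order statistic), 9 formfactor (shape), 10 Haralick
   statistics (offset-1 co-occurrence averaged over four angles), 144 GLCM
   (8 bases × 4 in-plane angles × 3 offsets + mean/SD aggregations over the
   angles per offset), 180 run-length (10 bases on the same grid), and 11
   size-zone features. Texture directions are the four in-plane angles
   applied per axial slice and accumulated over slices; `AllDirection` is
   the arithmetic mean and population SD (divisor 4) over them.
3. **Selection cascade** on the development split only: standardization to
   zero mean / unit population SD; per-feature two-class tests (Shapiro–Wilk
   at 0.05 in each class routes to the equal-variance t-test or Mann–Whitney
   U, keep p < 0.05); greedy Spearman redundancy elimination in ascending-p
   order at |ρ| < 0.9; and L1-penalized logistic regression with the penalty
   chosen as the minimizer of mean 10-fold cross-validated binomial deviance
   over a 100-point grid spanning four decades below the data-derived
   maximal penalty.
4. **Rad-score and combined model.** The rad-score is the LASSO linear
   predictor on the standardized selected features (an optional `refit` mode
   re-estimates unpenalized coefficients on the selected set). Clinical
   variables are screened univariately (continuous by normality-routed
   t/Mann–Whitney, ordinal collateral grade by Mann–Whitney, categorical by
   Pearson chi-square without continuity correction, Fisher exact when an
   expected cell is < 5); the combined model is a maximum-likelihood
   logistic fit of the label on the rad-score plus the screened variables,
   with a ridge fallback (penalty 1e-6) under perfect separation.
5. **Evaluation.** DeLong AUC standard errors and Wald 95% CIs (placement
   values with midranks, ties counted ½), the paired DeLong z-test, Youden-J
   operating points (ties resolved toward higher sensitivity, then lower
   threshold), McNemar on classification correctness (exact doubled-tail
   binomial when discordant pairs < 25, else continuity-corrected
   chi-square), Hosmer–Lemeshow with equal-frequency risk deciles and
   df = g − 2, decision-curve analysis on a 0.01 threshold grid with the
   beneficial range extracted as the longest contiguous interval where the
   model's net benefit exceeds both treat-all and treat-none, ICC(2,1)
   (inter-rater, absolute agreement) and ICC(3,1) (intra-rater, consistency)
   from the two-way ANOVA decomposition, and mid-rank Spearman screens
   between selected features and clinical covariates.

## Synthetic data: what it emulates and what it does not

No public imaging accompanies this problem, so the package ships a seeded
generator with two layers.

**Clinical covariates** are drawn per stratum from distributions calibrated
to the published stratum summaries: age is a truncated normal on [18, 100]
whose parent parameters are solved numerically so the *truncated* mean/SD
equal the configured values (75.17 ± 12.39 early, 70.12 ± 12.97 late);
NIHSS is a discretized log-normal matched to the stratum median/IQR;
ASPECTS is drawn from explicit integer probability vectors on 0..10 whose
median (IQR) are 8 (5–9) early and 6 (3–9) late; collateral grade uses a
pmf with median (IQR) 1 (1–1) in both strata; the boolean risk factors are
Bernoulli at the published prevalences. Replica mode draws exactly 46 early
and 77 late subjects so cohort composition is deterministic; a sampling
mode assigns strata at prevalence 46/123. The development/validation split
replicates the printed 85/38 sizes with largest-remainder stratification.

**Phantoms** are hemispheric ellipsoidal VOIs with an ellipsoidal hypodense
lesion: background ~35 HU brain tissue with spatially correlated Gaussian
texture (1.5 mm correlation length), a lesion HU decrement of 2 (early) or
4 (late) — late more hypodense — extra lesion texture of SD 1.5 / 2.5
(early/late) — late more heterogeneous — and a lesion volume fraction of
the VOI equal to 0.05 + 0.55·(10 − ASPECTS)/10, so lower ASPECTS means
larger lesions. Between-subject random effects keep the class distributions
overlapping, as subtle early ischemic change is: baseline density SD
1.5 HU, lesion decrement SD 2 HU, a lognormal texture-level spread
(relative SD 0.3), and a VOI scale with 4% jitter plus a −0.3%/year age
slope from age 70 emulating atrophy (this produces the negative
SurfaceArea–age correlation). A rater-perturbation operator offsets the
mask's signed distance field by a smooth random field (magnitude in units
of the mask's equivalent radius) for reliability studies.

The phantoms exercise every feature family and reproduce the *direction* of
the published group effects; they do not emulate scanner physics, skull or
CSF anatomy, hemorrhage, beam hardening, or the true covariance structure
of radiomics features in patients. Passing tests therefore demonstrate
algorithmic correctness and calibration of the generator, not clinical
performance; discrimination measured on phantoms has no bearing on real
cohorts.

## Numerical choices

- Seeding: a default master seed (20210123) with per-operation derived
  streams (master seed + stable stage/subject tokens), so any stage is
  reproducible in isolation; every CLI entry point takes `--seed`.
- Resampling aligns voxel centers at (k + 0.5)·spacing, with output extent
  round(extent/target); values at internal discretization bin edges go to
  the higher bin.
- Degenerate inputs: zero-variance features are excluded from
  standardization with a logged warning; zero marginal variance makes GLCM
  correlations 0 by convention; ICC with zero between-subject variance is
  reported as 0 with a flag; constant columns yield NaN Spearman ρ.
- The LASSO cross-validation path uses one warm-started scikit-learn saga
  solver per fold walking the descending penalty grid, with early path
  termination once the mean held-out deviance has clearly passed its minimum
  (more than 10 grid points past it and 5% + 0.02 above it) — smaller
  penalties only overfit further, so the grid argmin is unaffected. The
  final coefficients at the chosen penalty are refit with an exact
  L1-penalized optimizer whose intercept is strictly unpenalized, so the
  fully-penalized limit returns intercept = logit(prevalence) and the
  unpenalized limit matches the maximum-likelihood fit.
- The surface-area definition is exposed-voxel-face counting. Under this
  definition a digitized ball's surface converges to 3/2 of the smooth
  sphere's area, so the face-counted sphericity of a perfect ball converges
  to 2/3 (its maximum); the tests assert that voxelized limit. Meshed
  surface estimates are out of scope.
- Maximum 3D diameter reduces the candidate set to convex-hull vertices
  before the pairwise scan; the result is exact because the maximal
  inter-point distance is attained at hull vertices.

## Problem sizes used in the test suite

Simulation-based tests choose sizes that make their statistical claims
sharp while keeping the suite practical on one CPU: the generator
calibration checks use 10,000 subjects per stratum (3-standard-error
bands); LASSO recovery uses 100 seeds of n = 300 with 6 informative
(standardized effect 0.8 on the logit — a strongly discriminative feature)
+ 94 noise features; the combined-versus-radiomics comparison uses 100
seeds of the 123-subject replica with the generator's default tabular
effects (0.5 per SD for features, age and ASPECTS); DeLong CI coverage uses
1000 binormal replicates at n = 100/100; Hosmer–Lemeshow null uniformity
uses 200 seeds at n = 2000; the end-to-end image pipeline runs the full
123-subject cohort with 48³ phantoms once and verifies bit-level
determinism on a reduced replica.

## Known limitations

- The 396-feature inventory is a declared reconstruction: the commercial
  kit's exact membership, its run-length "offset" semantics (interpreted
  here as the ray sampling step) and its preprocessing constants are
  unpublished. The inventory is fixed by this package's default
  configuration and contains the six signature feature names verbatim.
- The redundancy stage's published survivor counts (218 → 8) are
  data-dependent and cannot be reproduced without the original patient
  images; the stage here implements the greedy |ρ| < 0.9 procedure with the
  threshold configurable.
- The in-plane four-angle direction model matches the published feature
  tokens; a 13-direction full-3D mode is not implemented.
- Hosmer–Lemeshow group counts follow pandas' quantile binning with ties
  grouped; with heavily tied risk scores fewer than g groups may form (df
  adjusts accordingly).
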