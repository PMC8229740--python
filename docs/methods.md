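# Methods

This note documents the models and numerical choices behind `radioprog`:
what each stage computes, which knobs matter, what the synthetic cohorts do
and do not emulate, and where the design was genuinely open.

## Synthetic cohorts

Real cohorts of this kind (pretreatment CT of recurrent/metastatic
head-and-neck tumors under immunotherapy) are not publicly downloadable, so
every pipeline stage is exercised on synthetic cohorts that reproduce the
*statistical structure* the analysis assumes rather than the appearance of
clinical CT.

Per patient the generator draws a binary survival label (1 = overall
survival ≤ 10 months, `event_rate`, default 0.3 — matching the minority
fraction seen in such trials), then conditions a single lesion on it:

- **Geometry.** A lobulated ellipsoid: semi-axes from a log-normal diameter
  (`base_diameter_mm` = 15, σ = 0.12, per-axis jitter 8 %), plus 2–4
  boundary spheres. Class 1 diameters are scaled by `volume_effect`
  (default 1.2), so mean *volumes* scale by its cube. Lesions are regrown
  if their rasterized bounding box falls under ~12 mm on any axis (they
  must survive 2 mm resampling and ±10 % bounding-box translations) and
  shrunk if they would touch the volume edge; both adjustments are logged.
- **Intensities.** Exterior: background 35 HU + white noise (`noise_sd`
  = 8 HU). Interior: tumor level 55 HU + a unit-variance Gaussian random
  field (Gaussian-smoothed white noise, smoothing length 2.5 mm) scaled to
  `texture_sd` = 6 HU, multiplied by `heterogeneity_effect` for class 1.
  The correlation length is above the 2 mm resampling grid so GLCM/GLRLM
  features can see it.
- **Clinical covariates.** Lesion count (1 + Poisson(2), median 3),
  affected organs (≤ lesion count by construction), performance status
  (32/65/3 % for 0/1/2), non-metastatic status (44 %), total tumor burden
  (largest lesion + 35 % per extra lesion). They follow the marginal
  structure of such cohorts but are *independent of the label*: the planted
  signal is imaging-only, which is exactly what makes the clinical-baseline
  comparison a negative control.

Volumes default to 64³ voxels at 1×1×3 mm — anisotropic, so resampling is
genuinely exercised. Lesion sizes and HU contrasts are deliberately at the
small/low end of the clinical range: they keep a full multi-seed cohort
study at desk scale (~15–25 s per 250-patient cohort on one CPU), and the
recovery criteria measure class *ratios* (volume and heterogeneity
effects), which do not depend on the absolute scale. Consequences: passing
tests demonstrate that the pipeline recovers a planted texture/volume
signal and stays at chance under the null — they do not demonstrate
robustness to scanner effects, contrast phases, segmentation ambiguity or
anatomy, none of which the generator emulates.

With `volume_effect = heterogeneity_effect = 1` the two classes are
generated from identical distributions (verified bitwise in the tests), so
the downstream test AUC has no signal to find; its mean over seeds
calibrates the null. Everything is a pure function of `CohortConfig`:
one `numpy` generator seeded from `seed` drives labels, geometry, texture
and covariates in a fixed order.

## Preprocessing

Denoising uses the discrete Gaussian truncated to a 3×3×3 voxel kernel with
σ = 0.5 voxel, renormalized to unit sum, with mirror boundaries (no
intensity is invented beyond the field of view). Denoising precedes
resampling. Resampling targets 2.0 mm isotropic spacing: cubic B-spline
(`scipy.ndimage.zoom`, `grid_mode=True`, so physical extent is preserved to
within one voxel) for intensities and nearest neighbor for the mask — a
thresholded-linear alternative would fabricate boundary voxels. The
pipeline crops each volume to the mask bounding box plus a 20 mm margin
before these steps; the margin exceeds the combined support of the
denoising kernel, the spline interpolator and the wavelet filters, so ROI
features are unaffected while cohort runtime drops by an order of
magnitude.

## Feature extraction (536)

Fixed-bin-width discretization assigns voxel v the level
`1 + floor((I(v) − min_ROI)/0.5 HU)`; the paper trail for radiomics
pipelines standardizes the bin width, not the anchor, and anchoring at the
ROI minimum makes levels shift-invariant. Families:

- **Shape (14, mask only, computed once per patient):** voxel-count volume,
  marching-cubes mesh volume/surface area (on the physical-coordinate
  mesh), sphericity, surface/volume ratio, maximum 3D and per-plane 2D
  diameters (attained on boundary voxels), and PCA axis lengths
  (4√λ) with elongation/flatness.
- **First-order (18):** moments (kurtosis is *non-excess*: a normal
  distribution scores 3), quantiles, energies, and entropy/uniformity on
  the discretized levels.
- **GLCM (24) / GLRLM (16):** distance-1 co-occurrences and maximal
  same-level runs over the 13 unique 3D directions; matrices are
  symmetrized (GLCM) and normalized per direction; every feature is
  computed per direction and averaged over non-empty directions.
- **Wavelet (8 × 58 = 464):** one-level undecimated separable
  decomposition (Coiflet-1 by default, configurable), bands labeled L/H per
  axis in (x, y, z) order; each band is rediscretized with the same bin
  width (each band has its own dynamic range) and scored with the 18 + 40
  intensity/texture features.

At 0.5 HU per bin the matrices have hundreds of levels, so they are never
stored densely: co-occurrence cells and runs are accumulated sparsely, and
feature formulas are reduced over the sparse support (a compiled kernel;
a plain-numpy implementation of the same definitions is kept in the
package and the test suite holds the two paths together, alongside
brute-force enumeration oracles). Two numerical shortcuts are exact:
for a symmetric GLCM the marginal entropies obey HXY2 = 2·HX, and the MCC
operator Q is row-stochastic with known top eigenpair (1, √p_x), so its
second eigenvalue is computed by deflated Lanczos iteration. The default
truncation (10 steps) keeps MCC within ~10⁻³–10⁻² of the dense
eigendecomposition (exact when the active-level count is small); an
accurate mode (80 steps, full reorthogonalization) matches dense `eigh` to
machine precision and is what the oracle tests use.

Degenerate inputs: a single-level ROI yields zero contrast-type features
and convention values for correlation-type ones (Correlation = MCC = 1,
entropies 0), flagged in the log; a zero-variance ROI makes
skewness/kurtosis NaN, and any patient with a non-finite feature is
dropped with a log entry while the cohort continues.

## Stability screening

Features are recomputed under the 6 axis-aligned mask translations of
`round(0.10 × bounding-box extent)` voxels plus the original mask —
7 measurements. The shift is floored at one voxel: on the 2 mm grid a small
lesion's bounding box can drop below 5 voxels, and a degenerate (identity)
perturbation would be no perturbation at all. Translated ROIs are exchangeable repetitions rather than
fixed raters, so the one-way random-effects single-measurement ICC(1,1) is
used: `(MS_b − MS_w)/(MS_b + (k−1) MS_w)`, which may be negative; a
zero-total-variance feature returns 1 (perfectly reproducible and
featureless — the z-score stage drops it anyway). Features with
ICC ≥ 0.75 pass. ICC is location/scale-free, so screening raw features is
equivalent to screening Z-scored ones; translation preserves the voxel
count, so mask-only features such as the voxel volume always pass. ICC is
computed on training patients only.

## Signature pipeline

Ordered stages, each frozen after fitting:

1. **Z-score** per feature with training mean/SD (population SD);
   zero-variance columns dropped. Test data always uses the training
   parameters.
2. **Redundancy pruning**: offending pairs (|Spearman ρ| > 0.85) visited in
   decreasing |ρ|; the member with the higher mean |ρ| to the other
   currently retained features is dropped, ties dropping the
   lexicographically later name. The decreasing-|ρ| visit order makes the
   outcome deterministic.
3. **AUC filter**: per-feature rank-sum AUC, orientation-corrected as
   max(A, 1−A) (a perfectly anti-ordered predictor is as informative as a
   perfectly ordered one — the same logic the evaluation applies to
   anti-predictive clinical variables), kept if strictly > 0.7. If nothing
   passes (a null cohort), the single best feature is kept with a warning
   so the downstream model exists and honestly performs at chance.
4. **SMOTE** balances classes by interpolating minority neighbors
   (x_i + u·(x_nn − x_i), u ~ U(0,1), k = 5 neighbors, reduced with a log
   entry when the minority is small). Synthetic points are used only to
   fit the LASSO and SVM — never for ICC, pruning, per-feature AUC, or the
   ROC threshold, which would leak fabricated structure into screening.
5. **LASSO**: L1-penalized logistic regression over a 50-point log-spaced
   λ grid (liblinear, C = 1/λ), λ chosen to maximize 5-fold stratified
   cross-validated AUC, ties resolving to the sparser model. If the winner
   has an empty support the smallest λ with support is used; if the
   support is empty everywhere all candidate features are retained —
   logged fallbacks that keep null cohorts runnable.
6. **SVM**: degree-3 polynomial kernel, C = 1, zero offset, kernel scale
   1/(n_features · var) — none of these are standardized in the field, so
   all are config-exposed. The raw decision value is the signature score.
7. **Threshold**: candidate thresholds are midpoints between adjacent
   distinct training scores (plus outside sentinels); the operating point
   minimizing √((1−sens)² + FPR²) wins, ties resolving to higher
   specificity. Thresholding uses the real training patients' scores, not
   SMOTE's synthetic ones. Calls are HR when score > threshold.

`SignatureResults` serializes to a single JSON document (normalization,
the four nested feature lists, λ and coefficients, support vectors,
threshold, seed); a reloaded model reproduces scores to 1e-12 without
sklearn state. Fitting never touches the test set, verified bitwise.

## Evaluation

Accuracy, sensitivity and specificity come with Wilson score intervals —
the score-test inversion, exact at the endpoints (the upper bound at
p̂ = 1 is algebraically 1). AUC is the trapezoidal area under the
empirical ROC, identical to the tie-corrected rank-sum statistic (asserted
against pair counting); its interval is a seeded stratified bootstrap
(2000 replicates) — a DeLong variance would be the parametric alternative,
but the bootstrap makes no tie assumptions at these small test sizes.
Clinical baselines use each variable as a one-dimensional score with the
same closest-to-corner threshold; variables with AUC < 0.5 have their
decision direction inverted first, mirroring the orientation-corrected AUC
filter. The signature-volume association is Spearman's ρ with the
two-sided t approximation p = 2·P(T_{n−2} > |ρ|√((n−2)/(1−ρ²))).

## Problem sizes and calibration studies

The recovery studies run the *entire* pipeline per seed. Defaults used by
the test suite and the acceptance script, chosen once as desk-scale study
conditions: planted-signal recovery and null calibration at 250 patients
(200 train / 50 test, 20 seeds each in the suite; the acceptance script
reports 5-seed means), and the heterogeneity dose-response
({1.0, 1.5, 2.5}, volume effect 1) at 55 patients × 20 seeds. Rare
degenerate seeds (a single-class split) are skipped and counted.

## Known limitations

- The generator plants signal only through lesion volume and stationary
  texture contrast; real prognostic signal is subtler and confounded.
- Shape complexity is limited to lobulated ellipsoids; boundary
  irregularity features are exercised but not stressed.
- The fast MCC truncation trades ~1e-3 absolute accuracy for an order of
  magnitude in runtime (exact mode available).
- SVM label-flip antisymmetry holds only to solver tolerance.
- No scanner harmonization, HU calibration, DICOM handling or multi-lesion
  segmentation; continuous survival times are out of scope (only the
  10-month binary label exists).
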