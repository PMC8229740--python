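# radioprog

A CT-radiomics prognostic pipeline for classifying 10-month overall survival
(OS) in patients with metastatic tumors, rebuilt as a tested, reusable
Python package and exercised end to end on synthetic 3D image cohorts with a
planted survival signal.

## The problem

Baseline clinical variables (lesion counts, tumor volume, performance
status) are weak predictors of which patients with recurrent/metastatic
head-and-neck tumors will survive beyond ~10 months on immunotherapy.
Radiomics asks whether quantitative texture and shape features mined from
the pretreatment CT of the largest lesion carry additional prognostic
signal. The workflow implemented here:

1. **Preprocessing** — 3D Gaussian denoising (3×3×3 voxel kernel, σ = 0.5)
   followed by resampling to 2 mm isotropic voxels (cubic B-spline for
   intensities, nearest neighbor for the lesion mask).
2. **Feature extraction** — 536 features per patient with fixed-bin-width
   discretization (0.5 HU/bin): 14 shape, 18 first-order, 24 GLCM + 16
   GLRLM texture features (distance 1, 13 directions, direction-averaged),
   and the 58 intensity/texture features on each of 8 undecimated wavelet
   sub-bands (coif1), 464 in total.
3. **Feature selection** — stability screening (ICC(1,1) ≥ 0.75 under
   ±10%-of-bounding-box ROI translations), Spearman redundancy pruning
   (|ρ| > 0.85 keeps the member with lower mean correlation), univariate
   AUC filter (orientation-corrected AUC > 0.7), then LASSO (L1 logistic,
   λ by stratified cross-validated AUC) after SMOTE class balancing.
4. **Signature** — a cubic-kernel SVM on the LASSO-selected features; its
   decision value is the radiomic score. The high-risk/low-risk threshold
   is the training ROC point closest to the ideal corner
   (sensitivity 100 %, FPR 0 %).
5. **Evaluation** — the frozen model is applied to a chronologically later
   test set: accuracy/sensitivity/specificity with Wilson 95 % intervals,
   ROC/AUC, six clinical-baseline classifiers (with direction inversion for
   anti-predictive variables), and the Spearman correlation between the
   signature and tumor volume.

Because no public imaging accession exists for such cohorts, the package
ships a first-class synthetic cohort generator (`radioprog.synth`): lesions
are lobulated ellipsoids filled with a correlated Gaussian random field
whose volume and texture contrast differ between survival classes by
configurable ratios (`volume_effect`, `heterogeneity_effect`). With both
ratios at 1 the classes are identical in law, giving an exact null for
calibrating the pipeline.

## Worked example

```python
from radioprog import CohortConfig, RunConfig, run_study

config = RunConfig(
    cohort=CohortConfig(n_patients=85, heterogeneity_effect=2.5, seed=1),
    seed=1,
)
result = run_study(config)          # ~15 s on one CPU
print(result.signature.summary())
print(f"test AUC      {result.test_auc:.3f}")
print(f"test accuracy {result.radiomics_report.accuracy}")
```

Output:

```
Radiomic signature - fitted pipeline
============================================
training patients        68
short survivors (label1) 20
stable features (input)  375
after redundancy pruning 69
after AUC filter (>0.7)   46
LASSO-selected           1   (lambda = 32.37)
SVM kernel               poly, degree 3, C = 1.0
score threshold (HR if >) -0.647287

selected features and LASSO coefficients:
  original_glcm_SumEntropy                                +0.4601
test AUC      0.962
test accuracy 0.88 (0.66-0.97)
```


85 patients split 68/17 chronologically; with a planted heterogeneity
contrast of 2.5× the selection funnel narrows 536 features to a single
co-occurrence entropy feature — texture entropy is exactly where the
planted heterogeneity lives — and the frozen signature separates the 17
held-out patients almost perfectly. Lowering
`heterogeneity_effect` and `volume_effect` to 1 removes the signal and the
test AUC collapses to chance — the calibration tests assert both regimes.

The same study is available from a shell:

```bash
radioprog run --config examples/demo.toml --out results/demo --seed 1
# or stage by stage: simulate | extract | fit | evaluate
```

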