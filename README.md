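# serafir

Chemometric case–control classification of ATR-FTIR serum
biofingerprints, built around the workflow used to screen for
osteosarcopenia in blood serum of older adults: mid-infrared spectra of
serum are preprocessed, reduced to a handful of informative features,
and classified into control vs. case with discriminant or kernel
models, reporting clinical figures of merit and the wavenumbers that
drive the separation.

The package is aimed at spectroscopists and chemometricians who want a
tested, scriptable version of this pipeline — including a synthetic
cohort generator, so every stage can be exercised and validated without
access to patient data.

## The pipeline

1. **Synthetic cohort** (or your own wide-CSV spectra): 62 subjects
   (32 control / 30 case) measured in triplicate; Gaussian absorption
   bands over 1800–900 cm⁻¹, class-discriminative band deltas planted at
   1711, 1661, 1574, 1510, 1398, 1273, 1225, 1107 and 906.5 cm⁻¹,
   per-subject polynomial baseline drift and per-replicate noise.
2. **Preprocessing**: Savitzky–Golay smoothing (5-point window, 2nd
   order), automatic weighted-least-squares (AWLS) polynomial baseline
   correction, truncation to the biofingerprint region, replicate
   averaging, and mean-centering fitted on training samples only.
3. **Split**: deterministic Kennard–Stone max–min selection,
   70 % training / 30 % test.
4. **Feature reduction**: PCA, X = TPᵀ + E (scores T, orthonormal
   loadings P), or the successive projections algorithm (SPA), which
   grows chains of minimally collinear wavenumbers and keeps the subset
   minimising the Mahalanobis cost
   G = (1/N_v) Σₙ r²(xₙ, m_true) / min_wrong r²(xₙ, m_wrong).
5. **Classification**: non-Bayesian discriminant scores
   L_ik = (xᵢ−x̄ₖ)ᵀ C_pooled⁻¹ (xᵢ−x̄ₖ) (LDA) and the per-class
   covariance analogue (QDA), assigning each sample to the class of
   minimal squared Mahalanobis distance; or a soft-margin SVM with RBF
   kernel K(x,z) = exp(−γ‖x−z‖²) solved by a deterministic SMO, with
   (C, γ) tuned by venetian-blinds 10-fold cross-validation.
6. **Validation**: accuracy, sensitivity, specificity,
   F-score = 2·SENS·SPEC/(SENS+SPEC) and G-score = √(SENS·SPEC) on the
   untouched test partition, plus peak picking on the first PCA loading
   to identify the discriminative wavenumbers.

## Worked example

```python
import numpy as np
from serafir import generate_cohort, preprocess_dataset, fit_pca, peak_pick
from serafir.pipeline import default_demo_config, run_pipeline

# full run: simulate -> preprocess -> split -> PCA-SVM -> figures of merit
report = run_pipeline(default_demo_config(seed=1))
print(report["table_markdown"])
print("peaks:", report["models"]["pca-svm"]["loading_peaks"])
```

prints

```
| FOM | **pca-svm** |
|---|---|
| AC | 100 |
| SENS | 100 |
| SPEC | 100 |
| F-SCORE | 100 |
| G-SCORE | 100 |
peaks: [1712.0, 1662.0, 1574.0, 1510.0, 1398.0, 1272.0, 1226.0, 1106.0, 906.0]
```

i.e. on the default synthetic cohort (planted effects ten times the
noise level) the cross-validated PCA-SVM separates the test partition
perfectly, and the first-loading peaks recover all nine planted
wavenumbers to within the 2 cm⁻¹ grid spacing.

The same run is available from the shell:

```sh
serafir simulate --seed 17 --out cohort.csv      # wide CSV + JSON sidecar
serafir run --config pipeline.yaml --seed 17 --out results/
```

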