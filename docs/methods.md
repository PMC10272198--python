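# Methods

This note records the models, numerical choices and known limitations
behind `serafir`, in the spirit of a statistical software appendix.

## Data model and synthetic cohorts

A spectral dataset is a matrix of absorbance rows on one shared,
strictly descending wavenumber grid, with per-row sample, replicate and
class metadata.  The generator emulates a two-class serum ATR-FTIR
cohort as

    a(w) = Σ base bands + [case] · Σ effect bands + baseline(w) + ε(w)

with Gaussian bands b(w) = A·exp(−(w−c)²/2σ²), a per-subject random
polynomial baseline (order ≤ 3, evaluated on the grid rescaled to
[−1, 1], coefficient SDs (0.02, 0.01, 0.005, 0.002) a.u.), and
i.i.d. Gaussian noise per replicate point.  Defaults: 32 control and
30 case subjects, triplicate measurement, grid 1800 → 900 cm⁻¹ at
2 cm⁻¹ (451 points; a full 4000 → 600 acquisition grid is available by
configuration, the analysis happens in the biofingerprint window
anyway), noise SD 0.005 a.u.  The nine effect bands sit at 1711, 1661,
1574, 1510, 1398, 1273, 1225, 1107 and 906.5 cm⁻¹ with |Δ| = 0.05 a.u.
(ten times the noise SD) and widths 8–10 cm⁻¹; their signs follow the
direction of the group differences the workflow is meant to recover
(controls higher for the amide/adenine/polysaccharide bands, cases
higher for the CH-deformation/phosphodiester/Z-DNA bands and the
1711 cm⁻¹ C=O band, whose direction we fixed as positive).

Randomness is hierarchical: subject *s* draws its baseline from the
stream keyed (seed, s) and replicate *r* its noise from (seed, s, r),
so enlarging a cohort never perturbs earlier subjects and a fixed seed
reproduces the cohort bit-identically.  Baseline drift is shared across
a subject's replicates while noise is not — this makes replicate
averaging meaningful (it shrinks noise variance by 1/R but not drift).

What the generator does *not* emulate: water-vapour/CO₂ lines, the
wavelength dependence of ATR penetration depth, scattering artefacts,
inter-subject biological variability beyond the planted class effect,
and band-shape asymmetry (bands are Gaussian; real amide bands are
closer to Voigt profiles).  Passing tests therefore demonstrate that
the *pipeline machinery* is correct and powerful enough to detect
effects of the planted size under drift and noise — not that real serum
cohorts separate this well.

## Preprocessing

Order is fixed: Savitzky–Golay smoothing → baseline correction →
truncation to 1800–900 cm⁻¹ (inclusive bounds) → replicate averaging →
(after splitting) mean-centering.

* **Savitzky–Golay** (default 5-point window, 2nd-order polynomial):
  implemented with `scipy.signal.savgol_filter(mode="interp")`, whose
  edge rule — fit the nearest full window and evaluate at the edge
  offsets — keeps output length equal to input without fabricating
  data, and reproduces polynomials of degree ≤ 2 exactly.
* **AWLS baseline**: an iterative polynomial fit (default order 2,
  fitted in a normalised coordinate for conditioning) in which points
  above the current baseline lose their upward pull.  The default
  `"clip"` variant refits to min(y, baseline): a point above the
  baseline still anchors the fit at the baseline level but cannot drag
  it up.  A strict 0/1 screen (`"binary"`: points above the fit dropped
  entirely) and a soft logistic weighting (`"soft"`) are selectable.
  The binary screen is well-posed on noise-free band-over-polynomial
  spectra, where the screened set grows monotonically until the band
  points are excluded; under noise, however, each refit to the kept
  (lower) half screens out roughly half of what remains, and after
  ~10 iterations the polynomial is underdetermined and the fit
  explodes — which is why it is not the default.  Convergence is
  declared when the coefficient vector moves by < 1e−6 in relative
  ℓ₂ norm (default cap 100 iterations); hitting the cap returns the
  last iterate with a `converged=False` flag rather than raising, since
  a slightly unconverged baseline is still usable and the flag is
  recorded.
* **Baseline before truncation**: correction runs on the full acquired
  grid, then the biofingerprint window is cut — the baseline estimate
  benefits from the wider support.
* **Mean-centering** is fitted on training rows only and applied to
  test rows; fitting on all rows would leak test information into the
  model.
* Normalisation variants (vector, SNV, min–max) exist as options but
  are off by default; in the emulated workflow they degraded accuracy.

## Splitting and model selection

Kennard–Stone picks the training set deterministically: seed with the
two most distant samples (Euclidean distance on the preprocessed,
replicate-averaged, *uncentered* spectra), then repeatedly add the
sample maximising the minimal distance to the selected set; ties break
to the lowest row index, and the training size is round(0.7·n) with
half away from zero (62 subjects → 43 train / 19 test).  The split is
unstratified, as in the emulated workflow; with very small cohorts this
can occasionally leave a partition single-class, which downstream
stages report as an explicit error rather than silently absorbing.

Venetian-blinds cross-validation assigns row *i* to fold *i* mod *k*
(default k = 10).  The number of principal components (1..10 by
default) and of SPA variables (1..15) is the value maximising mean CV
accuracy, ties to the fewest features; the SVM lattice C ∈ 2⁻⁵..2¹⁵,
γ ∈ 2⁻¹⁵..2³ (steps of ×4) is searched the same way with ties to the
smallest C, then γ.  Within each CV fold the centering and PCA are
refitted on the fold's training rows, so no fold sees its validation
rows during fitting.

SPA's validation samples for the cost G come from an inner
Kennard–Stone split (70/30) of the training partition — the test
partition is never touched before final evaluation.

## Reduction and classification

PCA is computed by SVD of the centered matrix (divisor n−1 is
irrelevant to variance *fractions*, which use σⱼ²/Σσᵢ² over all
singular values); each loading column is sign-fixed so its
largest-magnitude element is positive.  SPA builds, from every starting
column, a chain in which the next variable is the column of maximal
norm after orthogonal projection onto the complement of the chosen
columns; every chain prefix is scored by G on the validation samples
and the minimiser wins (ties: fewer variables, then chain order).
Columns whose projected norm falls below 1e−10 of the largest original
column norm are treated as collinear and never chosen.

LDA/QDA use the plain squared Mahalanobis distance as the
classification score — deliberately without the log-determinant and
prior terms of Bayesian discriminant posteriors — with the pooled
covariance Σₖ(nₖ−1)Cₖ/(n−K) for LDA and per-class covariances for QDA.
Any covariance with condition number above 1e10 receives a ridge
λ = 1e−8·trace(C)/dim, and the applied λ is recorded on the model.
When all class covariances are equal the QDA scores reduce to the LDA
scores exactly; the tests assert this to 1e−10.

The SVM solves the standard soft-margin dual (box 0 ≤ αᵢ ≤ C, equality
Σαᵢyᵢ = 0) by SMO with deterministic working-set selection: the first
index is the maximal KKT violator, the second follows the second-order
(largest dual decrease) rule, ties to the lowest index; multipliers
within 1e−12·C of a bound are snapped onto it so exhausted variables
leave the working sets.  The contract tolerance on the KKT gap is
1e−5; cross-validated lattice searches use a working tolerance of 1e−3
(configurable), because lattice corners with near-singular Gram
matrices (tiny γ) make the dual optimum nearly flat and the gap decay
sublinear — tightening the tolerance there costs orders of magnitude
more iterations without changing a prediction.  The bias is the mean of
yᵢ − Σⱼαⱼyⱼ K(xⱼ,xᵢ) over unbounded support vectors, or the midpoint of
the KKT-admissible interval when every multiplier sits on a bound (in
that degenerate case the bias is not unique and any admissible value is
a correct solution).  A decision value of exactly zero classifies as
+1.

Positive class is the case (osteosarcopenia) group, so sensitivity is
the case-detection rate.  Figures of merit are computed from unrounded
sensitivity/specificity; displayed tables round half away from zero to
integer percent.  The harmonic ≤ geometric ≤ arithmetic ordering of
F-score, G-score and (SENS+SPEC)/2, with equality iff SENS = SPEC, is
asserted property-style.  The best model maximises accuracy with ties
broken by G-score.  Loading peaks are local maxima of |loading| with
prominence ≥ 0.1 of the maximum (the default threshold is a choice;
the emulated workflow states no criterion).

## Problem sizes in tests and the acceptance script

Monte-Carlo checks use 20 seeds of the default 62-subject cohort.  For
the repeated PCA-SVM runs the hyperparameter search is a coarsened
lattice (C ∈ 2^{−5,−1,3,7,11,15}, γ ∈ 2^{−15,−11,−7,−3,1}, ×16 steps)
with 1–3 principal components (`default_demo_config`) — the planted
effects are strong enough that one component suffices, and the coarse
lattice keeps a full 40-run Monte-Carlo to a few minutes on one CPU.
Unit tests use smaller cohorts (16 subjects, 200-point grids) chosen so
the unstratified splits keep both classes in every partition.

## Known limitations

* The AWLS variant of the original commercial analysis software is
  proprietary; this implementation claims functional parity on the
  invariant suite, not numerical equivalence.
* Exact numerical agreement with commercial SVM toolboxes is likewise
  not claimable; correctness is established against the stated dual via
  an independent quadratic-programming oracle.
* Binary classification only; no probability calibration, ROC analysis
  or multiclass schemes.
* The synthetic cohort's effect sizes are calibrated to make pipeline
  properties testable, not to match any real cohort's signal-to-noise
  ratio; published real-data accuracies cannot be reproduced from
  synthetic data and are not claimed.
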