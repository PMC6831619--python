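# Methods

## Decoding model

Subjects are classified from local multivoxel patterns with a linear
soft-margin SVM. For a searchlight centred at voxel v, the feature
vector of subject i is the vector of that subject's map values at the
in-mask voxels within radius r of v (Euclidean distance between voxel
centres in world mm, inclusive; spheres at mask edges are truncated,
never discarded). The class convention is fixed globally — amusic = +1,
control = −1 — so decision-value signs are comparable across
searchlights and modalities.

Cross-validation is leave-one-subject-out: the SVM is trained on n−1
subjects and the held-out subject's signed decision function value is
recorded; this is repeated for every subject. Per-fold AUC is undefined
with one test case per fold, so "averaging over folds" is read as
pooling the held-out decision values and computing a single rank-based
AUC (Mann–Whitney, ties counted half); sensitivity and specificity come
from the sign of the pooled decision values. AUC, sensitivity and
specificity are assigned to the centre voxel.

Fixed analysis parameters, deliberately untuned:

| parameter | default | notes |
|---|---|---|
| searchlight radius | 12 mm | = 4 voxels at 3-mm isotropic; the value used for all modalities in the emulated design |
| SVM C | 1 | no nested cross-validation, no hyperparameter search |
| feature scaling | off | matching common decoding-toolbox behavior; optional z-scoring is fit on training folds only |
| label permutations | 1000 | group sizes preserved (relabelings are permutations of the observed label vector) |
| voxel alpha | 0.05 | threshold for both observed and permuted p-maps |
| cluster connectivity | 26 | configurable 6/18/26; echoed in every report |
| behavior permutations | 10,000 | shuffles within each diagnostic group |

## Permutation inference

The null is built by relabeling subjects and repeating the entire
searchlight analysis. Relabelings are sampled with replacement from the
balanced-assignment space (exhaustive enumeration when that space is no
larger than the requested count). Voxelwise p is one-sided (above-chance
decoding only): p(v) = (#{null AUC ≥ observed} + 1) / (n_perm + 1) under
the default include-observed (add-one) convention, so no p can be zero.

Cluster-size correction: each permutation's own p-map is computed by
ranking it against the pooled null (all permutation maps plus the
observed map — the permutation's own value is part of the reference),
thresholded at the same voxel alpha, and the largest suprathreshold
connected-component size recorded. An observed cluster's corrected p is
the add-one fraction of null max-sizes at least as large. Peaks are the
argmax within each significant cluster of the permutation z-score,
(observed AUC − null mean)/null SD (sample SD, n_perm null maps);
zero-SD centres are excluded with a warning, and ties break toward the
smaller linear voxel index, deterministically.

Two properties worth stating explicitly:

- **The LOO null is pessimistic, not centred at 0.5.** Holding a subject
  out leaves the training set imbalanced against its class, which tilts
  the hyperplane away from it; under shuffled labels the mean pooled
  AUC sits near 0.46–0.48 rather than 0.50 (identical behavior is
  obtained with libsvm directly; the test suite checks this). Because
  observed and null labelings pass through exactly the same estimator,
  permutation p-values remain calibrated.
- **At very small mask sizes the cluster test is conservative.** Null
  max-cluster sizes are small integers; heavy ties mean the attainable
  corrected p-values are a coarse grid and the realized family-wise
  rate falls somewhat below the nominal alpha. The effect shrinks as
  the mask grows and is negligible at whole-brain scale.

## SVM solver

The millions of tiny SVM fits required by the permutation stages
(spheres × folds × relabelings) are served by a purpose-built solver on
precomputed Gram matrices — one kernel per sphere, label-independent,
shared across folds and permutations:

- full fits use SMO with second-order working-set selection (libsvm's
  algorithm and stopping rule, KKT tolerance 1e-3);
- leave-one-out folds use an exact decremental-unlearning path: the
  held-out subject's alpha is retired along the piecewise-linear KKT
  trajectory, re-solving the free-set system at each bound-crossing
  event. Every fold solution is verified against the fold's KKT
  conditions at the solver tolerance; any degeneracy (empty free set,
  singular system, too many events, failed check) falls back to
  warm-started SMO. A subject with alpha = 0 in the full fit is not a
  support vector, so its fold solution equals the full solution — an
  exact shortcut.

All three routes satisfy the same KKT tolerance; route choice affects
speed only. Agreement of leave-one-out decision values with
scikit-learn's `SVC(kernel="precomputed")` (libsvm) is enforced in the
test suite over random problems including duplicated subjects, constant
features, and rank-deficient kernels.

## First-level maps

*Seed connectivity*: the seed series is the mean over a 5-mm-radius
sphere's voxels (a "10-mm-diameter" seed); the nuisance series (six
motion parameters, white matter, CSF) plus an intercept are regressed
out of the seed and of every voxel series (partial correlation — the
conventional reading of "regressors of no interest" in a correlation
analysis); the residual Pearson r is Fisher-transformed with r clamped
to ±(1 − 1e-7). Band-pass filtering (0.01–0.08 Hz) is a zero-phase hard
FFT mask with DC always removed. Tissue masks for nuisance extraction
are eroded by a cube (half-width three voxels per axis by default).

*Sparse-design GLM*: the hemodynamic response is estimated by FIR
("candlestick") regressors — an indicator per post-onset scan lag,
pooled over stimulus blocks regardless of condition — fit per voxel by
OLS; the FIR weights are averaged over the best-explained 10% of region
voxels (by candlestick R²). Condition regressors place those HRF
weights at each block's lags; nuisance regressors are an intercept, a
linear trend, and the first 10 principal components of white-matter
voxel series (centred and variance-normalized per voxel, so a few
high-variance voxels cannot dominate). The pitch contrast is
(low tones − low noise) + (high tones − high noise); the per-voxel t is
mapped to z through the exact t CDF (the residual degrees of freedom of
sparse designs are too few for the normal approximation, which remains
available as an option).

## Synthetic cohorts

The generator emulates the study design rather than scanner physics.
Per subject i, a latent severity s_i ~ Normal(μ_group, 1), with
μ_amusic − μ_control = Δ (the effect size, default 2). The subject's
map is smooth Gaussian noise — white noise convolved with a Gaussian
kernel (FWHM 6 mm default, matching smoothed-map inputs), wrap-around
boundary so the field is stationary, rescaled to unit voxel variance —
plus s_i · W, where W is a fixed unit-norm random pattern supported on
a sphere at a known coordinate. W depends only on `pattern_seed`; noise
only on `noise_seed`; severity and behavior only on `behavior_seed`.

Behavior: the MBEA-like diagnostic score is drawn from truncated
normals (amusic < 23 < control, matching the diagnostic rule; group
means 20.9/26.7, SDs 1.5/1.4); the pitch-discrimination threshold is
lognormal with group-dependent parameters (medians ≈ 0.64/0.19
semitones); the pitch-memory score is a + b·s_i + Normal(0, σ_b), with
a = 2.5, b = 0.4, σ_b = 0.45 by default. The synthetic pitch-memory
score is a severity-aligned *impairment* index (higher = worse), so the
default coupling is positive and the one-sided within-group permutation
test points in its conventional direction; only the relative structure
(group difference plus within-group severity coupling against noise)
matters for what the tests establish. A `verbal_memory` modality tag
forces Δ = 0 and b = 0 — the negative control. Resting-state and
sparse-design time-series generators add seed/target-coupled latent
signals and linearly mixed nuisance series so the first-level stages
are testable end to end.

What the generator does **not** emulate: hemodynamic nonlinearity,
physiological noise spectra, motion, registration error, multi-site
scanner effects (an optional additive site intercept exists, off by
default, since the emulated design minimized site differences by using
matched hardware). Passing calibration tests therefore demonstrates the
statistical machinery is correct under the stated model, not that real
data meet that model.

## Problem sizes used in the test suite

The statistical conditions of the calibration checks — 18 + 18
subjects, 200 replicates, 99-permutation nulls, voxel alpha 0.05, the
add-one convention, 26-connectivity — are kept as stated; the spatial
dimension is scaled to a single-CPU budget, which these checks are
insensitive to: family-wise error calibration runs on a 36-voxel mask
with a 4.5-mm searchlight; localization recovery on a 48-voxel slab
(effect size 2, ROI radius 4.5 mm, 49-permutation z-maps, success =
peak within ROI radius + searchlight radius); the circularity control
on 200 replicates of 36 subjects with 199 within-group permutations.
The demo analysis in `scripts/acceptance.py` uses a 14×14×12 grid at
3 mm (≈1200-voxel ellipsoid mask), a 9-mm searchlight and 99
permutations.

## Numerical choices and degenerate inputs

- Radii compare with ≤ (a voxel centre exactly on the sphere surface is
  included); voxel indices are 0-based; world coordinates are mm.
- NaN outside the analysis mask is permitted and never read; NaN inside
  the mask is an error at load time.
- Constant voxel series in connectivity maps give z = 0 with a counted
  warning; a constant seed series is an error.
- Constant feature columns and duplicated subjects are legal SVM inputs
  (soft margin); fewer than 3 subjects per class is an error (a
  training fold could otherwise lose a class).
- Exhaustive enumeration replaces sampling automatically when a
  permutation space (labelings, or within-group behavior shuffles) is
  no larger than the requested number of permutations; exhaustive
  p-values are exact fractions over the space (identity included),
  sampled ones use the add-one convention.
- Erosion by 0 voxels is the identity; an erosion that empties a mask
  warns rather than errors.

## Known limitations

- The (10-mm-diameter seed) localizer analysis is volumetric here; no
  equivalence with surface-based pipelines is claimed.
- `compare_correlations` treats the two samples as independent even
  when subject sets overlap (documented simplification).
- A McNemar comparison of classifiers requires paired binary outcomes;
  it is implemented on paired per-subject correctness, the nearest
  well-defined reading of comparing classifiers "on AUC values".
- The LOO pessimism and small-mask cluster conservatism described above
  are properties of the estimator and of tiny masks respectively, not
  adjustable knobs.
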