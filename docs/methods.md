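# Methods

`mkmri` implements a multimodal MRI classification pipeline: voxelwise
feature extraction (GMV, ALFF, ReHo), fusion of the three feature views
through a simplex-weighted multiple-kernel linear SVM, leave-one-out
cross-validation, and thresholded discrimination maps.  This note records
the model, the conventions chosen where several are in common use, the
synthetic-data design, and the limitations of what the test suite can show.

## Features

All features are computed inside a boolean whole-brain mask with `D` in-mask
voxels; subject-level maps are flattened to subject × voxel matrices using
one fixed voxel order (fastest-varying first axis), shared by all features
and subjects so classifier weights can be scattered back into volumes.

**GMV.** The structural volume is used directly as the gray-matter-volume
map.  It arrives smoothed (8 mm FWHM in the synthetic generator, matching
the heavier smoothing conventionally applied to modulated gray-matter
images) and is clipped at zero: volume is non-negative.

**ALFF** (amplitude of low-frequency fluctuations).  Per voxel, the time
series (after discarding the leading `n_discard` volumes and spatial
smoothing at 4 mm FWHM) is linearly detrended; the single-sided DFT
amplitude `a_k = 2|X_k|/n` is formed, and ALFF is the *mean* of `a_k` over
bins with `f_lo <= k/(n tr) <= f_hi`, boundaries inclusive.  Default band
0.01–0.08 Hz; with `n = 190`, `tr = 2 s` that is 27 bins (resolution
1/380 Hz).  Only the band is fixed by convention in the literature; the
detrend-then-mean-amplitude form used here is oracle-tested against a
direct per-bin DFT summation.  A constant series yields 0.  Each subject's
map is divided by its within-mask global mean (in-mask mean exactly 1).

**ReHo** (regional homogeneity).  Per voxel, Kendall's coefficient of
concordance over the 27-voxel neighborhood (voxel + 26 neighbors,
intersected with the mask; partial neighborhoods keep whatever in-mask
neighbors exist, minimum 2, else 0):

    W = 12 * sum_t (R_t - R̄)^2 / (K^2 (n^3 - n)),

with `R_t` the sum over the K series of the time-ranks at time t, average
ranks for ties, and *no* tie-correction factor in the denominator — the
form used by common resting-state toolkits.  ReHo is computed on the
unsmoothed series; the resulting map is globally mean-scaled and then
smoothed (4 mm), following the usual processing order (smoothing before
ALFF, after ReHo).  The vectorized implementation accumulates neighborhood
rank sums by exact shift-and-add, so it matches the per-voxel definition
bit for bit.

**Normalization.**  Per-voxel z-scoring with the population (divide-by-n)
standard deviation, fitted on the training rows only and applied to held-out
rows; columns constant on the training rows are flagged and mapped to zero.
Inside LOOCV the fit is per training fold by default (no leakage); a single
global fit is available behind `foldwise_zscore=False`.

## Multi-kernel SVM

One linear Gram matrix per feature is combined as
`K = sum_f beta_f k_f`, `beta` on the probability simplex.  Before
weighting, each Gram is divided by its mean diagonal (optional flag, on by
default) so the kernels share a scale and `beta` is comparable across
features.  The soft-margin dual on the combined kernel,

    max_a  sum a_i - 1/2 sum a_i a_j y_i y_j K_ij,
    s.t.   sum a_i y_i = 0,  0 <= a_i <= C,

is solved by SMO with maximal-violating-pair selection (KKT tolerance
1e-8; the loop is numba-compiled, with an identical pure-Python fallback).
The bias is the mean KKT estimate over unbounded support vectors
(`1e-6 < alpha_i < C - 1e-6`), falling back to the midpoint of the
feasibility interval.  `C = 100` everywhere by default; whole-brain linear
SVM performance is famously flat in C over a wide range, so no inner C grid
is searched.

Kernel weights are learned by alternating optimization: solve the SVM at
the current `beta`; then take a projected reduced-gradient step on `beta`
(gradient component `-1/2 sum_ij a_i a_j y_i y_j k_f,ij`, by Danskin's
theorem), with a golden-section line search on the same objective and exact
simplex projection (sort-based).  Only non-increasing moves are accepted, so
the objective path is monotone by construction.  `beta` starts uniform at
1/F.  Convergence: `max |dbeta| < 1e-4` or relative objective decrease
below 1e-4, capped at 100 outer iterations; line-search solves warm-start
from the incumbent dual point.  At convergence the relative duality gap of
the final combined-kernel SVM is checked (<= 1e-4 in the test suite;
typically ~1e-7).

For linear kernels the per-feature primal contribution is

    w^(f) = (beta_f / s_f) * sum_i alpha_i y_i x_i^(f),

with `s_f` the mean-diagonal scale, so the primal identity
`f(x) = sum_f <w^(f), x^(f)> + b` holds exactly (tested to 1e-8).

## Evaluation

LOOCV: each subject is held out once; normalization, Gram matrices, kernel
weights and the SVM are all re-fitted on the remaining subjects.
`sign(0)` predicts the patient class (+1), a documented deterministic
tie-break.  Sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)` and accuracy
`(TP+TN)/n` are reported in percent, rounded half-up to two decimals in
reports with full precision retained internally.  The ROC curve is built by
sweeping a threshold over the pooled LOOCV decision values (ties grouped);
its trapezoidal area equals the Mann–Whitney statistic, and is tested to
1e-12 against exhaustive pair counting.  The "improvement" statistic is the
combined-model accuracy minus the best single-feature accuracy, in
percentage points, differenced at reported (2-decimal) precision.

## Discrimination maps

Weight vectors from a fit on *all* subjects (per-fold averaging is not the
default: the map describes one model per comparison) are scattered back to
volumes; a voxel is retained iff `|w| >= theta * max|w|` over in-mask
voxels, `theta = 0.30` by default.  Maps are monotonically nested in
`theta`.  Weights are multivariate: retained voxels indicate relative
contribution to the decision function, never local statistical
significance.

## Synthetic cohorts

The generator emulates the study geometry: 17 patients (+1) and 20 controls
(−1), functional series of 200 volumes at `TR = 2 s` with the first 10
discarded, on a 12×12×12 grid of 3 mm isotropic voxels (desk-scale stand-in
for the 3 mm-resampled brain; `D = 1728` in-mask voxels with the default
full-grid mask).  The functional baseline is temporally white Gaussian
noise (`noise_sd = 1`); AR(1) noise is available (`ar_coeff`, off by
default).  Group effects are additive, box-shaped and patient-conditional:

* **volume** — structural mean shift inside the box, in noise-SD units
  (default 0.8, a strong but plausible morphometric group difference);
* **amplitude** — a 0.05 Hz sinusoid (in-band) at baseline amplitude
  `1.0 × noise_sd` for controls, raised fractionally for patients
  (default +50%);
* **synchrony** — a shared latent series mixed into every box voxel with
  coefficient `c` for patients (default 0.8; variance-preserving mixing
  `sqrt(1-c^2)·noise + c·latent`), 0 for controls.

Structural baseline is 5 noise-SD (clipping at zero is then negligible).
Default boxes are disjoint 4×4×4 regions.  All draws flow from one seed via
spawned per-subject substreams; identical configs are bit-identical.

What the generator does **not** emulate: MRI physics (no k-space, T1/T2
contrast), motion, physiological noise, spatial autocorrelation of the
noise background, anatomical structure, registration error, or site
effects.  Passing tests therefore demonstrate that the pipeline recovers
known injected effects under idealized noise — not that the reported
human-cohort accuracies are reproducible; effect sizes here are free
parameters, and no synthetic setting is claimed to reproduce the published
classification table.  Under the default (deliberately clear) effect sizes
the synthetic LOOCV accuracies saturate near 100% and the kernel weights
concentrate on the most informative modality.

## Numerical and design notes

* Gaussian smoothing uses `sigma = FWHM/(2·sqrt(2 ln 2))` per axis in voxel
  units with a periodic boundary, the rule under which the total sum is
  conserved exactly; `fwhm = 0` is the identity.
* Degenerate inputs: all-constant neighborhoods give ReHo 0; constant
  series give ALFF 0; constant training columns are zeroed after
  normalization; an all-zero weight vector yields an empty discrimination
  map (rather than a full one).
* Problem sizes in the test suite (cohorts of 8–37 subjects, grids of
  6³–12³, 20-seed Monte-Carlo loops) are the package's own desk-scale
  defaults; they keep a full run in roughly a minute on one core.
* Known limitation: under label permutation on cohorts *with* latent group
  structure, LOOCV accuracy of margin classifiers falls systematically
  below 50% ("anti-learning"; reproduced exactly by an independent SVM
  implementation).  The permutation-null check therefore uses effect-free
  cohorts, where the pipeline is verified to sit inside the 95% binomial
  band around chance.
* Open choices resolved here: fold-wise (not global) z-scoring inside
  LOOCV; ReHo from unsmoothed series with the map smoothed afterwards;
  pooled-fold (not per-fold-averaged) ROC; discrimination maps from a
  full-data fit; `beta` learned per training fold by the MKL objective with
  no nested hyperparameter grid.
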