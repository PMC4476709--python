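# Methods

## The model

The signature is a linear readout of a masked, vectorized activation
image. For an image `β` (one condition-level beta map, length = number of
in-mask voxels) the pattern response is

    PR = w · β + b

with voxel weights `w` and intercept `b` in the units of the training
outcome (rating units, 1–5, throughout). Correlation-based responses
(Pearson, Spearman, point-biserial for binary masks) are offered as
scale-free alternatives that ignore the intercept; they are the right
choice when comparing responses across datasets acquired in different
units or scanners.

### LASSO-PCR estimation

With far more voxels than observations, the weights are estimated by
principal-components regression with L1 selection:

1. center each voxel feature (no variance scaling: voxel units are
   homogeneous, and rescaling would re-weight voxels by noise level);
2. PCA to `k` components, default `k = min(n_obs − 1, n_voxels)`; an
   explicit `n_components` override exists because some study designs fix
   `k` to the number of *subjects* rather than rows, and the package does
   not take a position on which is preferable;
3. LASSO on the component scores. The penalty is chosen by inner 5-fold
   cross-validation along a penalty path (default) or fixed by the caller
   for exact reproducibility;
4. OLS refit on the components with nonzero LASSO coefficients, removing
   the shrinkage bias on the selected set;
5. back-projection: with selected loadings `V_s` and OLS coefficients
   `γ`, `w = V_sᵀ γ` and `b = γ₀ − μ·w` (μ = training feature mean), so
   voxel-space predictions `Xw + b` equal component-space predictions
   exactly (tested to 1e-6).

If the LASSO removes every component the model degrades to
intercept-only (the training mean) with a warning — a deliberate choice
over erroring, since this arises routinely in null simulations.

### Cross-validation and splits

The train/test split operates on subjects, never rows. Subjects are
sorted by their average rating and allocated systematically along the
sorted list with randomized rounding, giving groups whose mean-of-subject-
average ratings agree within 0.1 rating units for n ≥ 30 (resampled with
bounded retries otherwise). Training size is `round(fraction ×
n_subjects)`; fraction 2/3 of 182 subjects gives the 121/61 split used in
the headline design. Cross-validation is leave-one-subject-out: one fold
per subject, fold models never see the held-out subject's rows (a
leakage test perturbs a held-out subject's data and asserts identical
fold weights). Within-subject models use 5-fold CV over trials.

### Bootstrap voxel inference

The training sample is resampled with replacement and the full fit
repeated per resample. Two conventions are deliberate choices where the
procedure is otherwise underdetermined:

* **Resampling unit = subject** (default): whole within-subject row
  blocks are kept together, preserving within-subject dependence.
  Row-level resampling is available (`unit="row"`).
* **Penalty fixed from the full-data fit**: refitting the inner CV per
  resample is possible but expensive and adds selection noise to the
  weight distribution; with the penalty fixed, the bootstrap isolates
  sampling variability of the weights.

Per voxel, `z = mean/SD` of the bootstrap distribution and
`p = 2·Φ(−|z|)`. Degenerate voxels get `z = 0, p = 1` when mean and SD
are both zero, and a near-zero sentinel p (1e-300) when the SD is zero
with nonzero mean (all resamples identical — numerically certain signal).
Resamples in which the outcome is constant are redrawn. Thresholding is
`p < α` uncorrected or Benjamini–Hochberg FDR over in-mask voxels,
followed by removal of connected components smaller than `k` voxels
(defaults α = 0.001, k = 10, 26-connectivity; 6- and 18-connectivity
available).

### Classification statistics

*Forced choice*: within each subject the two conditions' responses are
compared; accuracy is the fraction of subjects where the designated
higher-intensity condition wins, ties credited 0.5, exact binomial test
against 0.5 on non-tied pairs. Sensitivity = specificity = accuracy by
construction, and the statistic is invariant to any strictly increasing
transform of responses.

*Single interval*: one observation at a time against a fixed cutpoint.
Candidate thresholds are the midpoints between adjacent sorted response
values, scanned exhaustively; the chosen threshold minimizes
|signal-detection response bias| `c = −(Φ⁻¹(TPR) + Φ⁻¹(FPR))/2`, with
rates clamped to `[1/(2n), 1 − 1/(2n)]` per class before the probit (the
standard log-linear correction for empty cells). Ties in |c| break toward
higher balanced accuracy, then toward the lower threshold. Accuracy is
balanced: `b = (TPR + TNR)/2`; it can fall below 50 % when the pattern
responds more to the nominally lower-intensity class, which is reported
as-is (signed convention).

Accuracy comparisons: McNemar's χ² on discordant pairs `(b−c)²/(b+c)`
for matched designs (p = 1 with a note when no pairs are discordant),
pooled two-proportion z for independent designs.

*Trend tests*: per subject, level means are projected on orthonormal
polynomial contrasts (QR of the Vandermonde basis, signs fixed so the
linear contrast increases with level and the quadratic is U-positive),
then tested across subjects with one-sample t tests.

### Subnetworks and virtual lesions

Contiguous thresholded regions are scored on each trial by the parent
map's weights restricted to the region (no intercept), ranked within
subject (average ranks for ties) and z-scored within subject — the
"normalized" step is z-scoring of ranks, a choice the package documents
because rank normalization alone would leave subject-specific scale.
All subjects' trial × region matrices are concatenated and regions are
clustered by Ward's minimum-variance linkage on Euclidean distance; the
partition is the tree cut at `cut_fraction × max merge height`
(default 0.31, exposed as a parameter since the fraction is a tunable
descriptive choice, not an estimate).

Virtual lesions act on the *thresholded* map (the sparse map is the
object whose regions partition cleanly): `remove` zeroes a cluster's
voxels, `only` keeps just them, the intercept is retained unchanged in
both. Consequently `remove + only − b = full` exactly (tested to 1e-10),
and single-cluster responses sum to the full thresholded response with
the intercept counted once.

## The synthetic-data generator

`simulate_dataset` draws, for subject `s` at rating `r`,

    β(s, r) = r · (effect_size + δ_s) · truth + noise_sd · ε,
    δ_s ~ N(0, subject_sd²),

where `truth` is a sparse signed pattern of contiguous smoothed blobs
(spheres of the requested voxel count, smoothed, re-thresholded to size)
and `ε` is white noise smoothed with a Gaussian kernel (FWHM default 3
voxels) and renormalized to unit marginal variance, so `noise_sd` is the
voxel SD regardless of smoothing. Smoothing uses wrap-around boundaries
to keep the noise field stationary. Rating availability per subject
mimics real self-report scales: each level is present with probability
0.98/0.88/0.98/0.88/0.80 for levels 1–5, so extreme levels are missing
for a subset of subjects and paired extreme-level tests run on reduced n.
A second modality (pain, levels low/medium/high) uses its own truth
pattern constrained to disjoint support, giving an exact double-
dissociation test bed. `simulate_timeseries` produces 4-D data whose
signal is a boxcar convolved with the canonical double-gamma HRF (peak
6 s, undershoot 16 s, undershoot ratio 1/6) — used only for chronometry
tests. Default sample sizes follow the target study design (182 emotion
subjects, 28 pain subjects, 30 trials); tests and the acceptance script
run 20–60 subjects on an ellipsoidal grid of ~2,000 voxels, the package's
chosen desk-scale problem size.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: physiological and motion artifacts,
spatial misregistration across subjects, non-Gaussian and temporally
autocorrelated noise, heterogeneous region amplitudes, first-level GLM
estimation error (rating-level maps are generated directly), and any
nonlinearity between neural response and reported rating.

## Numerical conventions

* Vectorization order is C-order over the mask's true cells — a pure
  function of the mask, tested by round trip.
* Grids must match exactly for all cross-image operations; a separate
  utility resamples (nearest-neighbor for masks, trilinear for continuous
  maps) and is never invoked implicitly.
* NIfTI-1 for images; intercepts live in a JSON sidecar keyed to the
  image filename (NIfTI has no intercept slot). Out-of-mask voxels are
  written as zero.
* Voxel indices are 0-based internally; world coordinates come from the
  affine.
* Every stochastic routine takes an explicit seed; a fixed seed fully
  determines simulator output, splits, bootstrap draws, and CV folds.
* Region ordering (size descending, then lexicographic minimum
  coordinate) is deterministic, so cluster labels are reproducible.
* The "ranked robust" spatial-correlation statistic is implemented as
  Spearman rank correlation, with a Huber-weighted fit on standardized
  ranks available (`ranked_robust`); the estimator is named but not
  defined in the source literature, so both variants are exposed.
* ROI-to-rating calibration for RMSE benchmarking of mean-activation
  predictors is a univariate linear model estimated on the training
  split only.

## Known limitations

* Bootstrap p-values use the normal approximation to the bootstrap z;
  percentile intervals are not implemented.
* The benchmark grid's emotion-vs-pain cell compares dot-product
  responses pooled across datasets; when the two datasets' units differ
  (different scanners), correlation-method responses should be used
  instead and are supported but not the default.
* Permutation null distributions and cluster-mass correction are out of
  scope, as are searchlight analyses and alternative learners (e.g.
  SVR).
* `published_table_metrics` expects a documented tidy schema; the
  released supplementary tables of any given study will generally need a
  small renaming step to match it.
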