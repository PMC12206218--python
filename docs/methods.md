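# Methods

This note documents the models, the numerical choices, the synthetic study
conditions, and the limits of what passing tests demonstrate.

## Classifiers and optimization

All six strategies minimize a convex objective built from per-domain **mean**
cross-entropies plus a quadratic penalty.  Using per-domain means (rather
than per-sample sums) gives the balanced-weighting trade-off parameter
`gamma` a sample-size-free meaning: `gamma = 0.5` weights the source and
target *domains* equally regardless of how many samples each contributes.

* `lambda_ridge` (default 1.0) penalizes the squared weight norm; the
  intercept is never ridge-penalized.  Note the penalty applies to the
  *mean* loss, so relative to a sum-loss formulation it is a strong prior —
  appropriate for the low-sample, moderate-dimension regime of per-sphere
  fMRI fits.
* `lambda_anchor` (default 1.0) controls the parameter-transfer (RTLC)
  refit.  Both weights **and intercept** are anchored to the source model:
  the anchoring concept covers all model parameters, and anchoring the
  intercept keeps the `lambda_anchor -> infinity` limit exactly equal to
  the source model.
* The solver is damped Newton with Cholesky factorization, Armijo
  backtracking, and a small epsilon slack in the line-search test (without
  it, the predicted decrease near the optimum falls below the float64
  resolution of the objective and the search would spuriously reject the
  final contracting steps).  Convergence criterion: gradient 2-norm
  <= 1e-8, at most 1000 iterations; fits are bit-reproducible.
* Binary labels only; classes are handled by stratified splitting and by
  scoring with balanced accuracy, not by loss weighting.  Prediction uses
  the tie rule score >= 0 -> class 1.

Feature augmentation (FA) triples the feature space — (x, x, 0) for source
rows, (x, 0, x) for target rows — and target prediction uses the
(general + target-specific) weight sum.  PRED appends the source model's
real-valued decision score as one extra target feature; the source model is
stored inside the returned model so prediction can re-derive the score
column internally.

## Cross-domain standardization

Both domains are z-scored with the **source** per-voxel mean and standard
deviation (population convention, divide by n), keeping the two conditions
on one comparable scale and applying the identical transformation to every
method being compared.  Standardization is computed globally over all source
samples.  Degenerate voxels (source sd < 1e-12) are kept (to preserve the
voxel-to-feature alignment the searchlight needs), set to 0 in both domains,
and reported via a warning and the returned parameter object.

## Trial-constrained validation

Volumes within a trial are temporally correlated, so trials are the
exchangeable units: no trial may straddle a train/test divide.

* Source: whole-trial splits, per-class `round(test_fraction * n_trials)`
  test trials (half-up rounding, minimum 1); default ratio 4:1.
* Target: exactly `N_t` training samples with approximate class
  stratification (`ceil(N_t/2)` / `floor(N_t/2)`; the class receiving the
  larger half of an odd `N_t` is chosen by a seed-dependent coin flip).
  The per-class quota is filled **trial by trial** in random order; the
  partially-used last trial's leftover volumes are discarded (recorded in
  the `SplitSpec` for audit) and the untouched trials form the test set.
  Filling trial-by-trial is what keeps a usable test set when `N_t` is a
  large fraction of the target data — sample-level uniform selection would
  touch every trial and leave nothing to test on.
* Partition p of a schedule uses seed `base_seed + p` (1-based), so any
  partition can be reproduced in isolation.

A deliberately ungrouped splitter (`splits.ungrouped_split`) is provided as
a diagnostic only.  With strong trial effects and zero class effect it shows
the optimistic bias the constraint prevents (~0.73 vs ~0.51 balanced
accuracy in the shipped demonstration).  A caveat worth knowing: even
grouped cross-validation on a *single fixed* dataset estimates 0.5 plus that
dataset's realized class-contrast luck (order 0.05 at study-scale trial
counts); the unbiasedness demonstration therefore averages over independent
replicate datasets, where it is exact.

## Searchlight

One sphere per in-mask voxel; membership is computed from integer voxel
offsets scaled by the isotropic voxel size, with an **inclusive** boundary
(`distance <= radius`), so counts match exact lattice enumeration: 123
voxels at 9 mm, 257 at 12 mm, 515 at 15 mm on a 3 mm grid.  Anisotropic
voxel grids are rejected.  For every sphere and partition the engine fits
the baseline (source-only), naive (pooled), and one adaptation classifier on
the sphere's columns, scoring balanced accuracy on held-out target trials;
the baseline is additionally scored on held-out source trials as a
within-domain ceiling.  Results are independent of sphere order, and
parallel execution (ordered reduction over partitions) is bit-identical to
serial.

The empirical null map re-runs the identical pipeline with target labels
globally shuffled, one fresh permutation per partition, preserving class
counts exactly and the partition-to-partition variance structure of the
observed maps.

## Map inference

* Variance smoothing: mask-aware Gaussian smoothing (numerator and mask
  smoothed separately, then divided), so constant maps are preserved
  exactly; default sigma = 6 mm.
* Two-sample pseudo-t: pooled variance, smoothed, then
  `t = (mean_a - mean_b) / sqrt(v_smooth (1/n_a + 1/n_b))`; zero-variance
  voxels with zero difference give t = 0.
* TFCE: one-sided (negative values contribute nothing), `E = 0.5`, `H = 2`,
  `dh = max/100`, 26-connectivity by default; all exposed in `TfceParams`.
  On a plateau the discrete sum converges to the closed form
  `extent^E * h^(H+1)/(H+1)` (within 2% at the default step).
* FWE control: max-statistic permutation over group relabelings with the
  add-one estimator `p = (1 + #{perm max >= obs}) / (n_perm + 1)`, giving
  valid finite-sample p-values in `[1/(n_perm+1), 1]`.  A paired sign-flip
  variant is available behind `paired=True`.
* Subject-level test: the specified two-sample permutation test on
  partition-level accuracies (observed vs null stacks) is provided as
  `subject_level_test`.  For region recovery the package prefers the exact
  **labeling-level randomization test** (`labeling_null_maps` +
  `max_stat_randomization_p`): L random *trial-level* relabelings of the
  target are each pushed through the identical pipeline over all partitions,
  and the TFCE-enhanced mean map is compared against the L null maps with a
  max-statistic.  Rationale: a finite target sample reused across partitions
  carries a fixed realized label-noise correlation ("luck floor",
  per-voxel bias sd ~0.04 at study scale) that any fixed classifier
  inherits; the partition-level null lacks it, so that test flags scattered
  luck voxels far above the nominal rate.  Under the labeling test, the true
  labeling is exchangeable with random trial relabelings when no voxel-label
  association exists, so observed and null luck have identical
  distributions and the test is exact (smallest attainable p is 1/(L+1)).

## Method comparison

Hypothesis tests use Friedman **aligned** ranks: values aligned by row mean,
all n*k values ranked jointly, Hodges-Lehmann statistic against chi-square
with k-1 degrees of freedom (degenerate all-equal tables report p = 1 with a
flag).  Pairwise post-hoc z-statistics divide column-sum differences by
`sqrt(2 D / (k - 1))`, where D is the omnibus denominator computed from the
data (including its row-sum correction) — the variance implied by the
omnibus statistic's own chi-square calibration.  Null simulation confirms
uniform pairwise p-values (4.8% below 0.05) and family-wise error 0.025 at
alpha 0.05 under exchangeable columns.  The Shaffer static step-down
correction uses the exact recursion for the possible numbers of
simultaneously true pairwise hypotheses (S(3) = {0,1,3},
S(4) = {0,1,2,3,6}).  Critical-difference displays use classical per-block
mean ranks (rank 1 = best); groups are maximal runs of rank-adjacent methods
with no significant pairwise difference.  Pooling across N_t values or
subjects is plain row-stacking.

## Synthetic study conditions

The generator mirrors the structure of a two-condition object-category
experiment at desk scale: a 12^3 grid of 3 mm voxels with an inscribed
spherical "brain" (912 voxels), 4 source runs and 2 target runs, 7 trials
per run per class, 7 volumes per trial (392 source / 196 target samples).
Each sample is `class_sign * pattern + u_trial + eps` with a
class-independent trial effect `u_trial` (sigma_trial = 0.5) shared by a
trial's volumes and white noise eps (sigma_noise = 1).

The source pattern beta is uniform over two informative spheres (9 mm
radius, ||beta|| = effect = 2.5, giving a whole-pattern Bayes balanced
accuracy Phi(||beta||/sqrt(sigma_trial^2 + sigma_noise^2)) ≈ 0.99 and a
per-7.5mm-sphere ceiling around 0.85-0.9, comparable to a strongly decodable
cortical region).  Concept shift rotates the class pattern by `phi` degrees
within the plane spanned by beta and a fixed unit nuisance direction
supported on a spatially **disjoint** nuisance sphere; `phi = 180` is a full
label flip.  Keeping the nuisance support disjoint means that under partial
concept shift the target-specific signal occupies different voxels than the
source signal, so a source-trained decoder carries literally zero
information about the rotated component — without this, random local
overlaps between source weights and the rotated pattern are large enough
(cos ~ d^-1/2 per sphere) to be flagged by the per-subject test.  Covariate
shift is parameterized by a scale (default 0.5: imagery patterns at half
the perception amplitude, matching the weaker signal of internally
generated activity) and an additive offset (default 0).  The
`GroundTruth` object reports the per-domain supports, patterns and Bayes
ceilings; sphere radii of 9 mm keep the region recoverable at Jaccard 0.3+
— a blob dilated by the searchlight radius d satisfies
Jaccard = (r/(r+d))^3, so r must comfortably exceed d.

What the generator does **not** emulate: hemodynamic convolution and delay,
scanner drift, physiological noise, spatial autocorrelation of the noise,
anatomical variability, multi-subject registration error.  Passing the
recovery test shows the pipeline is correct and calibrated under the stated
generative model, not that real imagery decoding will reach any particular
accuracy.

## Desk-scale run sizes

The shipped end-to-end recovery runs use the default synthetic config with a
7.5 mm searchlight (~57-voxel spheres), 6 partitions, N_t = 100, L = 20
null labelings, alpha = 0.05.  The 12^3 grid is roughly 15x smaller than a
brain, and the searchlight radius is scaled accordingly.  Null-calibration
checks use 40 repetitions (group FWE) and 2000 simulated tables (aligned
ranks).  The CLI defaults to 12 mm spheres and 100 partitions for
study-scale runs.

## Known limitations

* Binary classification only; the multiclass extension is out of scope.
* Linear decision functions only; no dimensionality reduction step.
* The paired-subject group design supports only the two-sample and paired
  sign-flip forms; no covariates.
* Hyperparameters (`lambda_ridge`, `lambda_anchor`, `gamma`) are fixed
  defaults, not tuned per sphere; a nested tuning loop would multiply the
  searchlight cost and is deliberately omitted.
* Sphere distances ignore the affine beyond the isotropic voxel size (no
  shear/oblique support); anisotropic data must be resampled first.
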