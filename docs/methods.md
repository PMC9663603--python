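# Methods

`rsapipe` implements a representational-analysis chain for multi-modal
object-vision experiments: a stimulus set is optimized so that five rated
object dimensions ("being alive", "looking like an animal", "having agency",
"having mobility", "being unpredictable") are as decorrelated as possible;
behavioural and brain response geometries are summarized as representational
dissimilarity matrices (RDMs); model RDMs built from single rating dimensions
are compared against data RDMs by rank correlation, with noise ceilings and
unique-variance partitioning; multichannel epochs are decoded pairwise over
time; and volumetric response grids are mapped with a searchlight.  All
stages run on synthetic data with planted ground truth, so every guarantee
the test suite states is a parameter-recovery statement.

## Synthetic data model

**Ratings.** Each stimulus has a latent score per dimension drawn from a
multivariate normal with a configurable correlation matrix (`target_corr`,
validated symmetric-PSD).  Latents (unit variance) are scaled by 10/3 onto
the −10..+10 rating scale, so ±3 sd span the range and clipping is rare.  A
participant's rating is

    rating = latent + bias(participant, stimulus, dim) + noise(presentation)

with `bias ~ N(0, 2.32²)` stable across repeated presentations and
`noise ~ N(0, 1.43²)` fresh per presentation, both clipped with the sum at
the scale bounds.  The two variances were calibrated analytically, once,
from the variance decomposition: with signal variance (10/3)² ≈ 11.1,
between-participant correlation = 11.1/(11.1+2.32²+1.43²) ≈ 0.6 and
within-participant repeat correlation = (11.1+2.32²)/(total) ≈ 0.89, the
consistency levels reported for human raters in this paradigm.  Clipping
attenuates both slightly (the generator measures ≈0.60 and ≈0.87 at the
default 300 stimuli × 26 raters).  The Gaussian noise shape is a stand-in;
real rating noise distributions are unknown, so tests passing here do not
certify behaviour under, say, bimodal or censored rating styles.  Defaults
follow the emulated study: 300 stimuli, 5 dimensions, 26 raters, 30
repeated stimuli, categories assigned round-robin over 100 category labels
(the first two tagged "human face" / "human body" so subset constraints are
exercisable).

**Subject RDM stacks.** Each subject RDM is a non-negative mixture
Σ wᵢ·modelᵢ plus Gaussian noise applied on the vectorized upper triangle and
mirrored (symmetry exact by construction); negative dissimilarities are
clipped to 0.  This is exactly the generative model the NNLS variance
partition assumes, which is the point: recovery failures then indicate
implementation defects, not model mismatch.

**Epochs.** Condition × trial × channel × time arrays. Each condition gets a
fixed random channel pattern with per-channel sd `effect_size`, added to
i.i.d. trial noise only at timepoints inside `effect_window_ms`; outside the
window all conditions share a zero mean and decoding is at chance by
construction.  Defaults mirror the emulated recordings (M = 30 trials, 64
channels, 1 ms sampling from −100 to 1000 ms); the boxcar window is a
deliberate simplification — real evoked responses wax and wane, so onset
estimates here only validate the inference chain, not biological latency
accuracy.

**Volumes.** A model RDM's geometry is planted in a region by classical MDS:
coordinates reproducing the model distances are rotated into voxel space by
a random orthonormal map and scaled by √n_roi, so per-voxel signal amplitude
is independent of region size and full-region condition distances equal
√n_roi × model.  The embedding is exact for Euclidean-embeddable models; for
arbitrary dissimilarities the closest Euclidean geometry (negative Gram
eigenvalues discarded) is planted.  A constant activation offset is added to
region voxels — it elevates the activation map used for ROI selection
without changing between-condition distances.

## Stimulus-subset selection (GA)

Fitness of a subset is the maximum absolute pairwise Pearson correlation
between dimension ratings (participant-mean ratings, since the selection
criterion concerns the average observer), plus `penalty_weight` (default 10,
far above the maximum base term of 1) per violated constraint: more than
`max_per_category` (default 2) stimuli of one category, or a required tag
("human face", "human body") missing.  Absolute correlation is used because
anti-correlated dimensions confound a design exactly as correlated ones do;
Spearman or signed variants would be defensible alternatives.  A dimension
constant within a subset has undefined correlations; its pairs contribute 0
with a warning so early random populations remain evaluable.

The GA evolves fixed-size subsets with tournament selection (size 3),
intersection-preserving uniform crossover (keep common members, fill from
the symmetric difference), per-gene swap mutation (rate 0.02, replacing a
member with a non-member), and elitism (2).  Population 200.  These
hyperparameters are not dictated by the emulated design (which specifies
only the subset size 128, 10,000 generations and 10,000 random baseline
draws); they were chosen for reliable convergence on exhaustively enumerable
instances and are all exposed in `GAConfig`.  Fitness is memoised per run on
the sorted subset, and populations are evaluated in one batched covariance
computation.  The random baseline reports the unpenalized base term of
uniform draws, matching how an unoptimized selection would be scored.

Grid coverage uses a sign rule: dimension bit = 1 iff the mean rating is
strictly positive, so the 0 boundary deterministically belongs to the
negative pole.

## RDMs and RSA

Dissimilarity is Euclidean distance between response patterns; for
single-dimension models, the absolute difference of participant-mean
ratings.  All stages share row-major upper-triangle vectorization.  Model vs
data comparison is Spearman's ρ with average-rank ties.  The noise ceiling
rank-transforms each subject's RDM vector (matching the Spearman inference
it bounds) and correlates each subject with the group mean including
(upper) or excluding (lower) that subject.  Note the upper bound does not
vanish for independent subjects — it concentrates at 1/√N (the
self-correlation share) — which is the standard behaviour of the
include-self estimator.

## Unique variance (NNLS)

The data dissimilarity vector is regressed on model vectors with
non-negative weights and a free intercept (profiled out by centering, which
is exact).  Predictors are scaled to unit variance before fitting so model
RDM scale cannot masquerade as explained variance (`standardize=False`
restores raw-scale fitting); the response is left raw rather than
rank-transformed — both choices are configurable because the convention is
not settled in the field.  R² is computed about the response mean and
floored at 0 (a constrained fit can do worse than the mean; the raw value
is logged).  Unique variance of model m is R²_full − R²_reduced(−m), each
from its own NNLS fit; it is nonnegative because the reduced feasible set is
nested.  Nuisance predictors (e.g. a low-level visual-feature RDM supplied
as an input file) stay in both full and reduced designs, so u_m is assessed
over and above them.

## Inference

Participant-as-random-effect throughout: Wilcoxon signed-rank against the
null value (50% for decoding accuracies, 0 for correlations and unique
variances).  Zero differences are discarded (classical treatment; the Pratt
variant is not implemented).  For effective samples ≤ 25 the p-value is
exact: the standard sign-enumeration distribution when absolute ranks are
untied, otherwise a conditional exact distribution obtained by convolving
the sign-flip distribution over the observed (average, possibly tied) ranks
— this keeps small-sample comparisons such as constant-shift score
differences exact instead of falling back to the normal approximation.
Larger samples use the normal approximation with continuity correction.
Multiple comparisons are handled by Benjamini–Hochberg at q = 0.05, with the
family defined per analysis: timepoints for time courses, all model pairs
for comparison panels, voxels for searchlight maps; each call site logs its
family.  Onset = earliest FDR-rejected timepoint, peak = argmax of the
group-mean curve (earliest on ties).  Standard errors on latencies are not
computed.

## Decoding

For each condition pair, timepoint and iteration: the M trials of both
conditions are partitioned by one shared random grouping into L = ⌊M/k⌋
pseudo-trials of k (default 5) raw trials each (remainders dropped, and
re-randomized each iteration so all trials are used in expectation); a
linear SVM (C = 1, no feature scaling — channels share units) is trained on
L−1 pseudo-trials per condition and tested on the held-out pseudo-trial of
each.  The held-out index is re-randomized per iteration; 100 iterations by
default.  Sharing one grouping between the two conditions makes accuracy
exactly invariant under swapping condition labels.  A decision value of
exactly 0 counts as incorrect (conservative and deterministic).

## Spatial mapping

ROI selection keeps the `n_top` (default 100) most activated voxels inside a
mask, ties broken by ascending linear index.  The searchlight sphere is all
in-mask voxels within Euclidean distance ≤ radius (default 4) in voxel units
on the integer grid — isotropic spacing is assumed, which holds for the
synthetic grids; anisotropic acquisitions would need a metric correction
that is out of scope.  Neighbourhoods are clipped by the mask and grid edge;
centers with fewer than 2 in-sphere voxels are skipped with a warning.  Each
sphere's condition × voxel patterns give a Euclidean RDM correlated
(Spearman) with the model; per-subject maps feed voxelwise Wilcoxon + FDR.
Because a sphere centered just outside a signal region still overlaps it,
localization tests judge hits against the region dilated by the radius.

## Orchestration and problem sizes

`run_pipeline` (and the `rsapipe` CLI) chains
simulate → select-stimuli → rdm → rsa → unique-variance → decode →
searchlight from a JSON config validated by a published pydantic schema,
writing per-stage artifacts with a manifest of parameters, per-stage seeds
(derived from one global seed) and SHA-256 content hashes; two runs with the
same config are bit-identical.

The test suite and the reproduction script run the same code at reduced
problem sizes chosen to keep planted effects dominant while completing on a
single CPU in minutes: GA checks use 1,000 generations and 1,000 baseline
draws on the full 300-stimulus catalog (and exhaustive comparison on pools
≤ 12); decoding uses 6–11 conditions, 10–20 ms sampling and 10–20
iterations; searchlight grids are 12³ at radius 2.  The reproduction script
fixes the subject count at 19, the emulated study's sample.  Scaling
iteration counts and generations back up changes precision, not the
qualitative recoveries.

## Known limitations

- Rating noise is Gaussian; clipping at ±10 slightly attenuates planted
  correlations and consistencies.
- The epoch model has no temporal autocorrelation, oscillations or channel
  covariance; decoding-latency recovery validates the statistics, not EEG
  realism.
- Volumes have isotropic voxels, no spatial noise smoothness and no
  hemodynamics.
- Non-Euclidean model RDMs are planted only up to their closest Euclidean
  geometry.
- Onset/peak standard errors are not estimated.
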