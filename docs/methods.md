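# Methods

## Experimental design

A session is 6 runs × 8 blocks × 8 trials across 4 spatial contexts
(rooms).  Each run visits every context exactly twice, in shuffled order.
A block shows the room interior for 7.75 s and then eight trials: task cue
0.25 s, compound face/object stimulus 1.5 s, inter-trial interval 4.25 s
(6 s trial pitch; 55.75 s blocks).  Two contexts are dominated by the face
task and two by the object task; the 75/25 contingency is realized
*exactly* as 6 congruent / 2 incongruent trials per block rather than by
independent Bernoulli draws, so the contingency is identical in every block
and the counts are testable.  The navigation period between blocks carries
no analyzed events and is not simulated; each block's timeline starts at
room onset, and onsets are per-run clocks.

## Learning models

Both learners use the delta rule P ← P + α(T − P) from a neutral initial
prediction of 0.5, with a fixed learning rate (the environment's
contingencies are stationary, so volatility-adaptive rates are out of
scope).  The **temporal** model maintains a single prediction across
context changes; the **contextual** model maintains one per room, updating
only the current room's learner.  The prediction error attached to trial t
is |T(t) − P(t)| with P(t) the prediction *entering* the trial — the
discrepancy between predicted and actual demand; a `lagged` flag provides
the variant in which trial t carries the previous step's error instead.

Learning rates are fitted per subject by exhaustive grid search
(0.01…0.99, step 0.01 by default).  For each rate pair, both PE series are
computed over the full trial sequence and log-RT is regressed on
{temporal PE, contextual PE, task, constant} over the filtered trials; the
SSE-minimizing pair wins, with ties broken toward the smaller contextual
then temporal rate (deterministic reruns).  The PEs enter this regression
raw; z-scoring is an affine map and cannot change the SSE ranking, so
normalization is applied only in the reported regressions.  The outcome is
mean-centered before the normal equations and ties are detected at
1e-9·var(y), which keeps the noise-free self-consistency exact without
mis-merging genuinely distinct lattice points.

## Behavioral analysis

RT analyses exclude error trials, post-error trials (post-error slowing is
a control process outside these models; a trial is post-error only if the
error occurred within the same block), and RTs more than 2.5 SD above the
median — one-sided, with median and SD computed over the correct,
non-post-error trials.  Whether the outlier statistics should be computed
before or after post-error removal is not determined by the procedure's
description; computing them after is the stricter reading and is what is
implemented.  Predictors are z-scored within subject with the sample-SD
(n−1) convention.  Log-RT uses the natural log (the base only rescales
coefficients).  Accuracy is modeled by maximum-likelihood logistic
regression; separation or non-convergence flags the subject, who is then
dropped from the group stage with a warning rather than aborting the run.
Group inference is a two-stage summary-statistics approach: one-sample
two-sided t-tests (df = n−1) on per-subject coefficients, Cohen's
d = mean/SD, and Benjamini–Hochberg q-values within the family of reported
behavioral effects; p-values are reported uncorrected with q alongside.

## Event patterns and noise normalization

Event amplitudes come from a per-run beta-series GLM: one stick regressor
per event (room onset, task-cue onset) convolved with the canonical
double-gamma HRF (nilearn's SPM form, peak-normalized) sampled at TR = 2 s,
plus constant/drift nuisance columns.  Estimated patterns are whitened as
β·Σ^(−1/2), with Σ the voxel residual covariance shrunk toward its diagonal
(default shrinkage 0.1 — event-rich designs leave few residual degrees of
freedom per run, and the whitening is computed per run because the GLMs are
per run).  The symmetric inverse square root comes from an eigendecomposition;
a singular Σ at zero shrinkage raises an error advising shrinkage.  The
pipeline's default path takes simulated event patterns directly — the GLM
path is exercised by dedicated tests on forward-convolved time series —
which isolates the similarity stages from GLM estimation noise.

Exclusion bookkeeping mirrors the behavioral filters: behaviorally excluded
trials are dropped from pattern analyses, a hook drops events within 12 s
before flagged outlier volumes (synthetic data plants none), and run 1 is
excluded from all reinstatement analyses because retrieval presupposes
learning; the context-representation validation test keeps all runs.

## Similarity analyses

All similarities are Fisher-z-transformed Pearson correlations computed
strictly across runs, with r clamped at 1 − 1e-7 so degenerate synthetic
inputs stay finite.  Context–trial pairs are labeled by context relation
(same context / same CTD / different CTD) and congruency — the trial's
required task against *its own* context's dominant demand (for
different-CTD pairs the alternative referent, context A's demand, merely
swaps the two congruency cells and leaves the interaction contrast's
magnitude unchanged).  Cell means are unweighted within subject; the 2:1
congruent:incongruent frequency imbalance is handled by the contrast
weights (+1, −1, +1, −1, −2, +2), whose zero sum and orthogonality to both
main effects are asserted at construction.

Trial-level reinstatement is the mean Fisher-z of a trial's same-context
and same-CTD pairs, signed by the trial's congruency (different-CTD pairs
are excluded so a demand mismatch between the two contexts cannot
contaminate the measure).  Block-level reinstatement is anchored at the
block's own retrieval event: the match/mismatch contrast (congruent-pair
mean minus incongruent-pair mean) over the pairs between *that block's
room-onset pattern* and out-of-run trials.  Anchoring at the room onset is
what makes the measure sensitive to that block's retrieval fluctuation;
averaging the trial-level values of the block's trials instead would pool
over all other blocks' onsets and carry no block-specific retrieval signal,
leaving the hippocampal coupling analysis nothing to explain.

Context–context similarity (all cross-run room-onset pairs, unordered) is
summarized per condition.  The validation test (same context > different
CTD, paired t) uses all six runs — no learning is presupposed; the
differentiation test (same CTD < different CTD) uses runs 2–6, matching the
run set of the reinstatement analyses, with per-run condition means
reported for the temporal profile.

## Brain–behavior regressions

All are per-subject OLS followed by group one-sample t-tests.  Trial-level:
log-RT on reinstatement with temporal PE, task and ROI-mean univariate
activity as covariates (optionally also contextual PE).  Block-level
coupling: cortical block reinstatement on hippocampal same-context,
same-CTD and different-CTD similarity plus hippocampal univariate activity,
with the cortical ROI's univariate activity as covariate; FDR across the
three similarity conditions.  Block-level predictors are z-scored within
subject (raw Fisher-z scales differ across subjects; z-scoring makes group
coefficients comparable).  The hippocampal-RT regression broadcasts the
block-level measures to the block's trials and signs them by trial
congruency (+1 match / −1 mismatch); a design with constant congruency is
rejected because the signed predictors would be confounded with their
unsigned versions.  The cross-subject analysis correlates mean hippocampal
same-CTD similarity with the behavioral CTD modulation strength (the
negated contextual-PE accuracy coefficient, so larger = stronger
modulation) across subjects.

## Synthetic-data generator

The generator is first-class code: every effect any analysis tests is a
named parameter, and the null configuration (`NeuralParams.null()` plus
zeroed behavioral betas) removes them all, which is what makes the
calibration suite meaningful.

**Behavior.**  log-RT = β₀ + β_t·z(PE_t) + β_c·z(PE_c) + β_task·task +
β_r·z(sign·gain) + ε, with PEs computed at the true rates (α_t = 0.30,
α_c = 0.10), sign the trial's congruency (±1) and gain the block's
reinstatement gain.  Accuracy is Bernoulli through a logistic link in the
same predictors.  Defaults: β₀ = 7.0 log-ms (≈1100 ms), β_t = 0.03,
β_c = 0.01, β_task = 0.057, accuracy logits 2.3 / +0.09 / −0.19 / −0.10 —
the group-mean effect sizes reported for this paradigm — with
between-subject coefficient SDs (0.02 for the RT betas; 0.25 and
0.15 + shared-latent slope 0.20 for the accuracy betas) chosen to
reproduce the implied group SEMs at n = 33.  Trial-level RT noise is
σ = 0.05 log-units: small enough that the between-subject dispersion
dominates the group-level statistics (keeping group d's at their empirical
scale) while leaving the learning rates identifiable from a single
subject's ~330 retained trials — at fMRI-realistic trial noise the
contextual rate is not recoverable from a 0.01 log-RT effect at this trial
count, and the package's recovery guarantees are stated at these
conditions.

**Patterns.**  Context codes are built exactly: an orthonormal, mean-zero
basis (QR with the constant vector projected out) mixed by the matrix
square root of the target correlation matrix, so noiseless codes realize
the planted correlations to machine precision (a non-PSD target raises a
configuration error).  Two further orthonormal directions are the face and
object task codes.  Trial patterns = context code + required-task code +
voxel noise; cortical room-onset patterns = context code + gain × dominant-
task code + uniform amplitude fluctuation; hippocampal room-onset patterns
= context code + overlap-fluctuation × same-CTD partner code + amplitude
fluctuation (no task code — the hippocampal ROI carries context identity
and excitability, not task content).  The gain of block b is
g_b = g₀ + γ_h·w_b + γ_u·u_b + noise, where w_b and u_b are the
hippocampal overlap and amplitude latents — the planted coupling.
Defaults: 60 voxels per ROI, voxel noise SD 0.35, cortical ρ_same-CTD = 0.2
vs ρ_diff = 0.0; hippocampal ρ_same-CTD = 0.22 in run 1 then 0.08
(differentiation emerging after first exposure) vs ρ_diff = 0.22;
g₀ = 0.4, γ_h = γ_u = 0.15, overlap SD 0.3, amplitude SD 0.2–0.3.  These
place the group effects at the effect-size scale typical of this
literature (interaction clearly detectable; differentiation and coupling
near d ≈ 0.5–0.8 at n = 33), and the overlap SD is large enough that the
block-level same-CTD similarity readout (≈8 cross-run partner pairs per
block) carries the planted fluctuation above pattern noise.  A subject-
level latent shifts the hippocampal same-CTD target (SD 0.08) and the
contextual accuracy coefficient (slope 0.20) jointly, planting the
across-subject similarity–behavior correlation.

**What the generator does not emulate:** scanner artifacts (motion,
outlier volumes — only the exclusion hook exists), hemodynamic variability
across regions, spatial autocorrelation between voxels, navigation
behavior, and session/run nonstationarities beyond the run-1 similarity
profile.  Passing tests therefore demonstrate that the *estimators* are
correct and calibrated under the assumed statistical structure, not that
the scientific effects exist in real data.

**Seeding.**  One master seed; per-subject streams derive from
SeedSequence(seed, subject-index) and split further into design, latent,
behavior and pattern streams, so any subject or stage can be regenerated
independently and bit-identically.

## Calibration and problem sizes

`calibration_suite` reruns the six group tests (two behavioral PE effects,
interaction, differentiation, two coupling coefficients) on replicate
datasets under the planted and null generators and reports rejection rates
with Wilson intervals; `permuted_rt_null` simulates a fresh group per
replicate and permutes each subject's log-RTs within the included set, so
its binomial interval is valid unconditionally (rates conditioned on a
single dataset are themselves random and would overdisperse).  The shipped
acceptance checks use 200 replicates at n = 33 subjects with 24-voxel ROIs
— the voxel count only scales measurement noise, and all planted effects
remain detectable at ≥ 98% power there — which keeps the full suite within
a desktop-scale run (~10 min).  The default pipeline run uses 60-voxel
ROIs and the full 0.01 grid.

## Known limitations

- The grid search is O(|grid|²) regressions per subject; it is fully
  vectorized over the lattice but still the slowest per-subject step.
- Logistic fits can fail to converge for extreme subjects (near-ceiling
  accuracy with few errors); such subjects are flagged and dropped from
  the accuracy group test rather than imputed.
- The GLM path models nuisance structure only as constant/drift/optional
  extra columns; real confound regression (motion, global signals) is out
  of scope.
- Reported group inference is the two-stage subject-then-group t approach
  throughout; no mixed-effects models.
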