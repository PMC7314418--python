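# Methods

This note documents the models and procedures implemented in `vdac`, the
choices made where several reasonable designs existed, and what the
synthetic-data tests do and do not establish about real recordings.

## The decodability statistic

The core quantity is a trialwise, time-resolved *distance difference*. For
a held-out trial with feature vector `x(t)` and training-fold class means
`mu_A(t)`, `mu_B(t)`, the decoder computes Mahalanobis distances

    d(x, mu) = sqrt( (x - mu)'  Sigma(t)^-1  (x - mu) )

and reports `delta(t) = d(x, mu_other) - d(x, mu_own)`: positive when the
trial lies closer to its own class mean in the whitened space, i.e. when
the classes are decodable. The square-rooted distance (not the squared
quadratic form) is used, and the difference is taken on the square-rooted
distances.

`Sigma(t)` is estimated per timepoint from all training trials of both
classes with a Ledoit–Wolf shrinkage estimator toward a scaled identity,
`S* = (1 - lambda) S + lambda (tr S / f) I`, with the analytic shrinkage
intensity clipped to [0, 1]; this guarantees invertibility even with more
features than trials. The training trials are demeaned by their own class
mean before estimation: the estimator pools class-demeaned residuals from
both classes (the within-class noise covariance, as in LDA), which keeps
class signal out of the noise estimate while still using every training
trial. The vectorised per-timepoint implementation is numerically
identical to the scalar Ledoit–Wolf estimate (unit-tested against
scikit-learn's).

Cross-validation uses stratified random k-fold splits (k = 5), repeated 50
times by default (10 in the reduced cohort analyses) with deltas averaged
over repeats per trial. Stratification is a deliberate hardening: with
unequal class counts, plain random folds can produce a fold without one
class. `k = n` is supported as an explicit unstratified leave-one-out path
for oracle tests. The repeated splitting re-estimates covariances per
repeat — the literal reading of the repeated-splitting procedure. One
master seed expands to per-repeat fold seeds and is logged in the result's
params.

Per-trial delta timecourses are smoothed with a Gaussian kernel,
sigma = 16 ms, truncated at ±3 sigma and renormalised at epoch edges (so a
constant timecourse is a fixed point and no edge attenuation occurs).

Before decoding, channels are re-expressed with PCA (70 components by
default, capped at the data rank), fitted per participant on all trials
and timepoints jointly. The fitting scope is a package choice; fitting on
everything at once is label-blind, hence leakage-free.

## Decoding schemes

* **Location** — side of the reward stimulus (left vs right), identities
  collapsed, decoded separately for high- and low-reward trials; their
  contrast is the value modulation of spatial selection. In the learning
  task the high condition pools high-vs-zero and high-vs-low choice
  trials.
* **Identity** — which of the two same-value stimuli appeared, decoded
  within each cue side (so side information cannot contribute) and pooled
  across sides, per reward level.
* **Value (cross-generalised)** — train high-vs-low on stimulus pair 1
  (H1/L1), test on pair 2 (H2/L2) and vice versa, sides collapsed. Both
  directions are run and each usable trial is tested exactly once;
  averaging the two directions halves the variance at no cost over a
  single fixed train/test direction. In the learning
  task the high-vs-low choice trials are excluded and the doubled
  low-vs-zero trials are halved by an odd/even split so class counts
  match.
* **Trialwise learning correlation** — per participant, the Spearman
  correlation between trial number and the trial's delta at the peak time
  of the *group-level* trial-averaged curve (peak chosen per condition,
  ties to the earliest time), Fisher-z transformed.

Attention-task decoding pools the 500 and 1000 ms SOA trials (cue-locked,
uncontaminated by target processing for the first 500 ms) and treats the
0 ms SOA separately.

## Group statistics

Significance over time uses cluster-based permutation tests: per-timepoint
t statistics thresholded at the two-tailed critical value for the
cluster-forming alpha (0.05), cluster mass = summed t within a contiguous
suprathreshold run, and family-wise control from the permutation
distribution of the maximum absolute cluster mass — participant sign flips
for one-sample/paired tests, group re-partitions for the independent
(median-split) test. Conventions fixed here: two-sided thresholds and a
two-sided max-statistic null (the conservative default when a directional
hypothesis is not imposed); the +1 rule for p-values, so the smallest attainable
p is exactly 1/(n_perm + 1); mass rather than extent as the cluster
statistic. Baseline (pre-onset) timepoints are cropped before testing.
Under a symmetric null the sign-flip test is exact; its empirical
family-wise error rate is verified by simulation in the test suite.

Brain–behavior analysis correlates the per-participant VDAC interaction
with the neural contrast at every timepoint (Spearman), with the
cluster-forming threshold converted from alpha through the t
approximation of the rank correlation's null, and a permutation null from
independent shuffles of the behavioral vector (one shuffle per
permutation, shared across timepoints, preserving the neural temporal
dependence). The *skipped* variant removes bivariate outliers per
timepoint before correlating: centre = coordinatewise median (a
documented, swappable choice among the family of robust centres used by
skipped-correlation estimators), one projection direction per data point
through the centre, and the box-plot rule with ideal-fourths quartiles and
1.5 × IQR fences applied to every projection; a point flagged on any
projection is excluded, and the observed per-timepoint exclusions also
apply during permutation. When nothing is flagged the skipped estimate
equals the plain Spearman correlation exactly.

Post hoc power for a correlation test uses the plain Fisher-z
approximation (z = atanh(rho), SE = 1/sqrt(n-3)). This is deliberately the
simple approximation: it gives 81.4% for rho = 0.5 at n = 30 (the
conventional "80% power" anchor) and sits roughly 1.5 percentage points
below the exact-distribution power at these sample sizes, which is the
tolerance used when the tests cross-check it against a bivariate-normal
Monte Carlo.

The median split sorts participants by their effect; the lower half is
the weak-capture group, with an odd median participant joining the upper
(strong) half and ties broken by participant index.

## Univariate components

Epochs are baseline corrected (200 ms prestimulus) *before* the planar
root-mean-square combination, because RMS is nonlinear and would otherwise
bake the baseline into the envelope. Trial averages are computed per cue
side first and RMS-combined afterwards. Sensors of interest are selected
per participant from a contrast orthogonal to the tested one (activity
averaged across reward levels): the five posterior combined sensors per
hemisphere with the largest absolute contralateral-minus-ipsilateral
difference in the component window. The N2pc is the contra-minus-ipsi
average within 200–325 ms; the P1 uses a per-sensor peak latency (largest
strict local maximum within 75–200 ms, falling back to the window maximum
when no interior peak exists, plateau ties to the earliest sample) and a
50 ms window around it, clipped at epoch edges. "Posterior" and
"hemisphere" are metadata labels on the channel table; no sensor geometry
is modelled.

## Behavioral analysis

Learning curves are trailing 10-trial moving averages within session
(shrinking at session starts, no leakage across the boundary), sessions
concatenated, with the high-reward curve pooling high-vs-zero and
high-vs-low trials. Attention-task summaries use the median RT of correct
trials per reward × congruency × SOA cell, with per-SOA
baseline-subtracted difference scores (the per-SOA subtraction is a
package choice; the alternative global subtraction only shifts all scores
by a constant). The VDAC interaction first averages the four reward ×
congruency cells across the three SOAs (unweighted, immunising the effect
against unequal correct-trial counts) and then computes
(high_incong − high_cong) − (low_incong − low_cong). Group-level ANOVAs
and t tests are delegated to standard statistical routines.

## The synthetic paradigm generator

The generator reproduces the two-phase experimental design exactly for
every seed: per learning session 96 high-vs-low, 96 high-vs-zero and 192
low-vs-zero choice trials (the doubling equates selection frequency);
per attention session 60 trials per reward(2) × congruency(2) × SOA(3)
cell plus 60 baseline trials per SOA, 1800 trials over two sessions.
Identities, zero-reward partners and left/right placement are
counterbalanced exactly within cells rather than drawn Bernoulli — exact
balance removes schedule-level confounds that random placement would leak
into the decoders — and only presentation order is randomised.

Epochs follow a ramped pattern-superposition model,
`data = sum_k s_k a_k(t) p_k + noise`, with unit-norm mutually orthogonal
channel patterns and logistic ramps (ramp 50 ms; the onset latencies are
the meaningful parameters, the logistic rise shape is a smoothness
choice):

| component | onset | amplitude | notes |
|---|---|---|---|
| location | 100 ms | 1.0 | contralateral posterior support; ×(1 + m_i) on high-reward trials from 260 ms |
| identity | 125 ms | 0.8 | equal across reward levels (the empirical null); a config gain can plant a modulation |
| value axis | 336 ms | 0.5 | sign +1 high / −1 low / 0 baseline; shared across identities and sides |

m_i ~ N(0.5, 0.25) truncated at 0 is the participant's latent neural
value-modulation gain. In the learning task the high-reward location
amplitude additionally grows as a saturating exponential of trial number
(floor 0.4, tau 128 trials) — any monotone law satisfies the reported
positive rank correlation; this one is smooth and bounded. Noise is a
rank-8 spatial factor model (drawn per participant, so pattern-specific
SNR asymmetries average out across the cohort) driving stationary AR(1)
series (phi = 0.9 at 250 Hz) with marginal SD 2.0 per channel. These
amplitudes were fixed once to give single-trial decodability in the range
typical of sensor-level MEG (trial-mean delta of order 0.1–0.5 against
unit-free whitened distances) and strong but not saturated group effects.

Behavior couples to the neural gain: the latent RT interaction is
`b_i = kappa m_i + N(0, sigma_c)` (kappa 60 ms by default, sigma_c 8 ms),
entering RTs as ±b_i/2 on high-reward incongruent/congruent trials on top
of a base RT (550 ms), a linear SOA preparation benefit (60 ms/s) and
Gaussian trial noise (150 ms). The low-reward congruency term defaults to
0 ms, matching the absence of a reliable low-reward capture effect; with
zero RT noise the estimated interaction equals b_i exactly. Error rates
are a flat lapse (6%) plus an extra 5% only in high-reward incongruent
long-SOA cells, mirroring the accuracy signature of capture. Learning-task
behavior (choice accuracy rising along a saturating curve ordered by value
difference, RTs speeding with practice) is generator plumbing so the
learning-curve analysis has realistic input.

All stages draw from an explicit seed block (schedule / patterns / noise /
behavior); cohorts are bit-reproducible, and the latent truth (m_i, b_i)
is returned in a separate table that analysis code never reads.

### What the synthetic tests do and do not show

Passing recovery tests establishes that the pipeline measures what it
claims under a known generative model: onsets recovered within ±24 ms
(1.5 smoothing sigma), null contrasts stay null at the nominal rate,
couplings are detected when planted and absent when not. Real MEG differs
in ways the generator deliberately omits: no sensor geometry or forward
model, no eye-movement/cardiac artifacts, no trial-to-trial latency
jitter or amplitude drift, noise that is Gaussian and stationary, and
planted patterns that are exactly orthogonal. Results on synthetic data
therefore validate the *analysis*, not any empirical claim about cortex.

One subtlety of the generative design is worth knowing: cross-generalised
value decoding is not perfectly blind to the value modulation of the
location signal. The high-reward class mean carries a (1 + m)-scaled
location component; collapsing across cue sides cancels it to first order
only, because distances are norms, leaving an O(m²) contribution that
generalises across stimulus pairs from the 260 ms modulation onset. With
the default mean gain (0.5) this can pull the detected value-decoding
onset earlier than the planted 336 ms value-axis onset at some seeds — an
inherent property of amplitude-modulated signals under distance-based
cross-generalisation, not an implementation artifact.

## Problem sizes used in tests and the acceptance script

Cohort-scale computations run at a reduced, fixed scale chosen once: 30
participants, one attention session (60 trials per design cell), 32
channels, epochs −100..+500 ms at 250 Hz, 10 cross-validation repeats,
1000 permutations, 500 Monte Carlo runs for the error-rate calibration.
The brain–behavior recovery scenario uses strong coupling
(kappa = 80 ms, coupling noise 4 ms) with reduced RT noise (40 ms), i.e. a
regime where the planted relation should be clearly detectable.

## Known limitations

* Temporal clustering only; no sensor-space adjacency clustering or TFCE.
* No temporal-generalisation (train-time × test-time) matrices and no
  nonlinear decoders.
* The skipped-correlation outlier rule is one member of a family; other
  robust centres (e.g. MCD) would flag slightly different point sets.
* The permutation p-values inherit Monte Carlo resolution 1/(n_perm + 1);
  onset estimates inherit the 4 ms sample spacing and smoothing blur.
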