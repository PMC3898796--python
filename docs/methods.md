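# Methods

## Subjective distributions

A subject's prior over the stimulus feature space is represented as a finite
Gaussian mixture,

    P(x) = sum_k w_k N(x; mu_k, Sigma_k),

on a 2-D feature space bounded at ±4 SD per dimension (the box over which
densities are discretized, compared and plotted). The mixture family is a
modeling choice, not a claim about the brain: it is flexible enough to
express the multimodal, nonconvex priors the method is designed to detect,
while keeping every observer likelihood analytic — the convolution of a
mixture with Gaussian perceptual noise is again a mixture, so the latent
perceived and underlying stimuli integrate out in closed form. Components
are not truncated to the box; grid operations renormalize over it instead.
Truncation would break the analytic marginals, and for priors whose mass is
concentrated well inside ±4 SD the difference is negligible. The default
component count is K = 3; K is fixed per fit, with model choice left to
cross-validated prediction if a user needs it.

## Ideal observers

Both tasks share one perceptual front end: the perceived stimulus is the
presented stimulus plus isotropic Gaussian noise with SD `perceptual_sigma`
(SD units, shared across tasks and hypotheses). Correlated or anisotropic
noise would be a natural extension, but a single scalar keeps the model
identifiable from choice data alone.

**Familiarity (2AFC).** Hypothesis k: stimulus k is a noisy sample from P,
the other stimulus is uniform over the box. The hypothesis likelihood is
u · sum_m w_m N(s*_k; mu_m, Sigma_m + sigma_p^2 I) with u the uniform box
density. The uniform face's own perceptual-noise convolution is approximated
by u itself; the neglected edge effect is of order sigma_p / half_width
(about 1/8 at the defaults) and affects both hypotheses symmetrically.

**Odd-one-out (3AFC).** Hypothesis k: the pair {i, j} are two noisy
realizations of one sample from P and stimulus k is a noisy realization of
an independent second sample:

    L_k = N(s*_i; s*_j, 2 sigma_p^2 I)
          · sum_m w_m N((s*_i+s*_j)/2; mu_m, Sigma_m + sigma_p^2/2 I)
          · sum_m w_m N(s*_k; mu_m, Sigma_m + sigma_p^2 I).

Because the two accounts of a stimulus pair (one underlying face vs two)
spend different numbers of samples from P, their odds scale with the local
density of P: observers discriminate more readily near high-probability
regions. This is the mechanism that makes equidistant triads informative
about P at all.

**Decision stage.** p = (1 − lapse) · softmax(temperature · log L) + lapse/n.
Temperature and lapse are both inferred, so the sampler can explain an
imperfect responder either as soft (low temperature) or as sharp-but-lapsing;
only their combined effect on choice probabilities is identified, which is
all that prediction needs. No stimulus-position or order biases are modeled.
All likelihoods are computed in log space with a floor of exp(−745).

The alternative odd-one-out rules (`ooo_by_familiarity`, choosing the most
or least familiar face as the odd one) reuse the per-stimulus familiarity
scores and exist to test whether the two tasks share a decision rule — they
are deliberately wrong-headed comparison models, not part of the main model.

## Priors and inference

The posterior over (P, Omega) is sampled in an unconstrained
parameterization with the priors (defaults in parentheses):

| parameter            | transform        | prior |
|----------------------|------------------|-------|
| mixture weights      | additive log-ratio | symmetric Dirichlet (alpha = 2) |
| component means      | identity         | N(0, 2^2 I) SD units |
| covariance eigen-scales | log           | log-normal (median 0.6 SD, log-scale 0.5) |
| covariance rotation  | angle mod pi     | uniform |
| perceptual sigma     | log              | log-normal (median 0.5 SD, log-scale 0.5) |
| temperature          | log              | log-normal (median 2, log-scale 0.75) |
| lapse                | logit            | Beta(1, 9) |

These are weakly informative on the scale of the ±4 SD box: means anywhere
plausible in the box, component SDs from ~0.2 to ~2, perceptual noise from
~0.2 to ~1.2 SD. The covariance parameterization (log eigen-scales plus a
rotation angle) is specific to 2-D spaces, the only configuration exercised.

Sampling is random-walk Metropolis-within-Gibbs over seven blocks (weights,
means, eigen-scales, angles, and the three observer parameters). Proposal
scales adapt multiplicatively toward 25% acceptance during burn-in only
(default burn-in 25% of steps), so detailed balance holds exactly for
retained draws; post-burn-in draws are thinned to at most 2,000. All
randomness flows through one seeded generator and runs are bit-reproducible.
Initialization follows the prior (means drawn from their prior, scales and
observer parameters at prior medians, angles uniform); among 32 such
candidates the one with the highest initial log posterior starts the chain,
which avoids occasional starts in regions so flat the chain wastes its
burn-in. Proposals for temperature and lapse reuse the cached hypothesis
likelihoods, since those parameters enter only the decision stage.

The hypothesis-likelihood code was verified against brute-force quadrature
oracles (Gauss-Legendre over the latent faces, scipy per-component
densities) to relative 1e-5 across randomized priors, observer parameters
and stimuli; label permutations of the mixture leave the log posterior
exactly invariant, so only label-free summaries (grids, predictions) are
reported.

## Synthetic observers

The simulation module defines the study conditions for every recovery and
transfer experiment:

* Ground truths are K = 3 mixtures with component means placed uniformly in
  the box (inset 0.5 SD so modes remain representable), minimum pairwise
  separation 2.5 SD, flat-simplex weights, eigen-SDs uniform on 0.3–1.0 and
  random orientations — multimodal priors that differ strongly between
  synthetic subjects.
* Observer parameters: perceptual sigma 0.5 SD, temperature 3, lapse 0.05 —
  a responder that is clearly informative but far from deterministic.
* Familiarity stimuli are independent uniform pairs in the box. Odd-one-out
  trials are 90% equilateral triads (uniform center and orientation, side
  1–4 SD, vertices inside the box by rejection) and 10% independent uniform
  triples. A configurable fraction of trials (default 10%) is presented
  twice under a shared repeat group; repeats are answered independently,
  which is exactly why consistency scores fall below 1.
* Default budgets are 1,000 trials per task for single-subject recovery and
  500 per task for cohort experiments with a 3,000-step sampler — sizes at
  which the end-to-end pattern is stable in minutes on one CPU. These are
  configuration, not empirical claims.

What the generator does *not* emulate: human response biases (position,
order, sequential effects), non-Gaussian or correlated perceptual noise,
learning or drift over the session, and any particular relation between the
feature space and real face appearance. Passing tests therefore demonstrate
that the inversion machinery is correct and well calibrated under its own
assumptions — that the method *can* recover complex priors from realistic
trial counts — not that human priors are mixtures or that human noise is
Gaussian. Synthetic consistency scores (≈0.8–0.9 at these settings) run
higher than typical human values, making synthetic subjects somewhat easier
to predict than real ones.

## Downstream analyses

**Comparison.** Grids (default 100×100; discretization error is orders of
magnitude below between-subject differences) are compared by JS divergence
with base-2 logs so the maximum is exactly 1 bit. Task invariance is tested
per task by a one-sided Wilcoxon rank-sum comparing the n_subjects
same-subject/cross-task distances against the different-subject/same-task
distances; if all distances are zero the comparison is degenerate and p = 1
by contract. MDS is classical (Torgerson double-centering) on √JS — a true
metric, unlike raw JS — deterministic up to per-axis sign, fixed by making
each axis's largest-magnitude coordinate positive; negative eigenvalue mass
above 10% of the spectrum triggers a warning rather than an error.

**Prediction.** Posterior-predictive response probabilities average the
observer's response distribution over all retained draws. Across-task
prediction transfers the fitted Omega along with P: the claim under test
concerns P, and refitting Omega on target-task data would leak target-task
information into the prediction. Performance is reported as the mean
probability assigned to actual choices (threshold-free); a hard-accuracy
variant exists and is used for bound comparisons, where a ceiling on
accuracy is the natural object.

**Consistency bound.** Consistency is the fraction of same-stimulus
presentation pairs answered identically, pooled over repeat groups. Under a
symmetric response model (majority option probability p, remainder split
equally) consistency is c = p² + (1−p)² for two alternatives and
c = p² + (1−p)²/2 for three, giving the ceiling p = (1+√(2c−1))/2 or
(1+√(6c−2))/3 on any predictor's expected accuracy. The symmetric split for
the three-alternative case is a modeling choice; by Jensen's inequality the
resulting bound remains an upper bound in expectation even when the true
non-majority probabilities are unequal.

**Baselines.** The moment-matched predictor replaces each posterior draw's
mixture by the single Gaussian with the same mean and covariance (law of
total covariance) before averaging — identical pipeline, second moments
only. The discriminative baseline is a squared-exponential-kernel
probabilistic classifier (Nystroem features + logistic regression, kernel
width and regularization by seeded cross-validated grid search) on
concatenated stimulus coordinates, with task symmetries built in by
augmentation (stimulus swap for familiarity, cyclic rotations for
odd-one-out) and enforced at prediction by averaging over the same group.
It fits one task's stimulus-response mapping directly and therefore cannot
transfer across tasks; asking it to raises an error, which is the point.

## Numerical choices and edge cases

* Grid masses renormalize after discretization; resolutions below 8 are
  rejected. JS treats 0·log 0 as 0 via `rel_entr`.
* CSV round trips preserve floats exactly (shortest-repr writing,
  `float_precision="round_trip"` parsing).
* `log_posterior` returns −inf (never raises) for parameters outside prior
  support; note the unconstrained parameterization puts zero density on
  lapse ∈ {0, 1} and on zero weights (the transform Jacobians vanish there).
* Equilateral-triad and separated-mean placement use rejection sampling with
  capped retries; infeasible geometry raises with a clear message.
* `moment_match` returns K = 1 inputs unchanged, making idempotence exact.

## Known limitations

* Inference assumes the fitted K; it does not select it. Fits with K larger
  than the truth recover the density well (extra components shrink or
  overlap) but per-component summaries are meaningless — only grid-level
  summaries are exposed.
* The sampler is a random-walk method: for sharply concentrated posteriors
  (thousands of trials) short chains under-mix, and recovery quality is then
  limited by mixing rather than information. Default chain lengths are
  matched to the default trial budgets.
* Only 2-D feature spaces are exercised; density math is dimension-generic
  but the covariance parameterization and all tests are 2-D.
* The consistency bound assumes stationary response probabilities across
  repeated presentations; drift or learning would bias it upward.
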