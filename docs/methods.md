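# Methods

## Task model

A session is four blocks of 36 trials (144 in total).  Each block fixes a
true self-performance level and runs through three signalled phases:

| phase | trials | known | inferred |
|---|---|---|---|
| Self-Other | 16 | control (instructed) | self, other |
| Self-only | 4 | control = 1 | self (confirmation) |
| Control-Other | 16 | self | control, other |

The only outcome signal is the feedback
`feedback = self*control + other*(1-control)`.  The other player's
trial score is drawn from a Normal around its scheduled level (SD 6.5,
truncated to 0–100), and that level changes without announcement on the
12th within-phase trial.  On Self-only trials the feedback equals the self
score exactly.

**Objective-error mapping.**  Game performance enters as a non-negative
objective error with a half-Normal distribution (scale `error_sd`,
arbitrary game units).  Errors map to the 0–100 self-score scale through a
logistic `score(e) = 100 * sigmoid(-slope * (e - midpoint))`, calibrated
per block: the midpoint solves for the scheduled mean self level and the
slope solves for a trial-wise score SD of 5 — the performance variability
the observer models take as true.  Errors at or beyond an extremity
threshold (2.5 error-SDs) are detected as active disambiguation (AD) and
force a score of exactly 0, whether the error was deliberate or
accidental.  For high scheduled levels the solved midpoint can lie beyond
the AD threshold; this is benign because AD detection is a separate
criterion, not the logistic tail.

**Schedules.**  Generated schedules stratify self levels across blocks
(one block per equal-width stratum of the configured range, shuffled) and
assign the paired-phase control levels without replacement;
`generate_schedule_variants` additionally rotates Control-Other levels
over self strata as a latin square so that, across a cohort running the
variant set, self and control are decorrelated by design.  This mirrors
the role of a pre-determined, counterbalanced schedule; i.i.d. level draws
can leave self and control confounded within a four-block session, which
makes the control-inference interaction unidentifiable.

## Observer models

All three observers are sequential Bayesian learners over (self, other,
control, sigma_self, sigma_other) with the likelihoods

* normal trial: `feedback ~ N(self*control + other*(1-control),
  sqrt(sigma_self^2*control^2 + sigma_other^2*(1-control)^2))`
* AD trial: `feedback ~ N(other*(1-control),
  sigma_other*(1-control))`

and differ only in the trial-type assignment: Active (correct), Ignorant
(every trial treated as normal), Passive (AD trials discarded; a learner
that has seen only AD trials reports its prior, flagged `prior_only`).
Priors are Normal, centred on the first-trial ratings, with SD 30 for the
performances and 0.3 for control; the sigma priors are half-Normal(5)
(the positive-scale reading of a Normal(0,5) prior on a standard
deviation).  In Self-Other the control is clamped to the instructed value;
in Control-Other the self level is clamped to truth with sigma_self = 5;
on Self-only trials only (self, sigma_self) remain free, and an AD trial
there is skipped as information-free (feedback is deterministically 0).
From the 12th within-phase trial the other player is re-estimated as a new
player: the other dimension of the joint posterior is marginalised out and
re-initialised with a Normal prior centred on the most recent posterior
mean, SD reset to 30.  The reset discards posterior correlations between
the other level and the remaining parameters, which is the price of a
closed-form re-initialisation; sigma_other is retained since the new
player's trial-to-trial variability is task-controlled, not
player-specific.

**Inference backend.**  The joint posterior is tracked on a fixed lattice
(101 points per performance axis, 41 for control, 16 for each sigma on
0.25–15) and updated trial by trial; because the posterior after `t`
trials is the prior times the first `t` likelihoods, the sequential filter
reproduces the repeated refit to trials `1..t` exactly.  Posterior
summaries (means, SDs, central 90% credible intervals) come from the grid
marginals with linearly interpolated quantiles.  Two-trial instances agree
with an independently coded 201-points-per-dimension brute-force posterior
to well within 2% of each parameter range (asserted in the tests).  An
MCMC backend is not provided; the grid filter is deterministic, fast, and
exact enough for every analysis in the package.

**Observation-noise floor.**  The likelihood SD carries a 1-score-unit
floor added in quadrature, representing the display granularity of the
feedback score.  Without it the density is unbounded on the
`sigma_other -> 0` ridge wherever an AD feedback is matched exactly, and
noise-free instances (such as the alternating 44/4 worked example)
concentrate posterior mass at spurious exact-fit combinations; with the
floor the worked example converges to the analytic control of 0.8.

**Uncertainty.**  Trial-wise uncertainty is the phase-dependent average of
90% credible-interval widths: `(w_self + w_other)/2` in Self-Other and
`(100*w_control + w_other)/2` in Control-Other; on Self-only trials the
self width is used alone.  Estimates are rating-aligned throughout: the
value reported for trial `t` is the posterior after trials `1..t-1`, i.e.
the belief held while rating at the start of trial `t`.

## Synthetic agents

Agents carry an Active-learner belief state, seed each phase's priors with
noisy gut-feeling first ratings (SD 10 around the scale midpoint; the
known self level in Control-Other), and read out posterior means as
ratings with truncated Gaussian noise (default SD 5 for performances, 0.05
for control).  AD is stochastic:
`P(AD) = clip(base + gain * uncertainty/100, 0, 1)` with defaults base
0.08 and gain 0.40, multiplied by 0.1 on Self-only trials.  Deliberate AD
draws an error beyond the detection threshold; accidental AD arises from
the natural error tail (~1%).  Under the defaults the cohort shows ~20%
AD on paired phases and ~4% on Self-only trials, matching the qualitative
phase pattern.  Cohorts draw mildly heterogeneous agent parameters,
rotate four counterbalanced schedule variants, and record a debrief-style
AD count (true per-game count plus rounded Gaussian noise, floored at 0).
Per-participant randomness comes from `SeedSequence` child streams of one
master seed, so a cohort is fully reproducible from its seed.

What the generator does **not** emulate: human sub-optimality in credit
assignment (agents are rational Bayesian readers of their own beliefs),
reaction times, motivational or strategic heterogeneity beyond the
parameter jitter, and memory or attention lapses.  Consequences observed
in the pipeline and deliberately not asserted as tests:

* the estimated-feedback accuracy does *not* improve more over a phase
  than the individual rating accuracies — rational agents with ~20% AD
  identify the individual levels themselves, so the headroom that human
  raters leave is absent;
* the self-update gain is not monotone in control for a Bayes-optimal
  learner once AD trials pin the other player, so the positive
  tPE-by-control interaction seen in human credit assignment is not
  reproduced by the agents (the positive tPE main effect is).

## Behavioural statistics

Derived measures follow the task arithmetic: estimated feedback is the
ratings-implied feedback (instructed control standing in for the control
rating in Self-Other); rating accuracy is `1 - |rating - true| /
max(100-true, true)` on a common 0–100 scale; the total prediction error
`tPE = feedback - estimated feedback` splits into `sPE = tPE*control` and
`oPE = tPE - sPE`, making `sPE + oPE = tPE` exact to the bit; switch
trials are trials whose AD status differs from the previous trial, and the
feedback difference on a switch trial is always normal-minus-AD feedback;
inverse self is `ln(1/self rating)` with ratings floored at 1.

Per-participant regressions are OLS with predictors z-scored on the
analysed subset: credit assignment (rating update on previous-trial tPE,
control, their interaction and trial number; normal Self-Other trials),
and the lagged-AD models for uncertainty and summed rating errors (AD at
t−1 and t−2, trial number, other-changed and phase; the other-changed
regressor is included in both because the unannounced change inflates both
outcomes late in the phase, where AD is also elevated).  The first trials
of a phase drop out of lag-based models.

Control inference runs on Control-Other switch trials only (participants
with fewer than 3 excluded): next-trial control rating on feedback
difference, inverse self, their interaction and the current control
rating, all predictors standardized across participants.  The default
backend is the deterministic two-stage fit (per-participant OLS, group
one-sample t-tests per coefficient); `hierarchical=True` fits a linear
mixed model (random intercept and feedback-difference slope) instead.
Substituting the three observers' control estimates for the ratings
discriminates them by sign: the interaction (and the feedback-difference
main effect) is positive for the Active learner, negative for the
Ignorant learner, and near zero for the Passive learner.  At 30 agents
the Passive learner's small mechanical negative component can
occasionally reach nominal significance under reseeding; the sign
separation of Active and Ignorant is stable.

Group-level wrappers: mixed ANOVA (between: sample; within: stated
factor) via pingouin with eta-squared, reducing to a within-only RM ANOVA
with a warning for single-group input; two-tailed one-sample t-tests with
Cohen's d and 95% CIs; Spearman correlation with a CI for the debrief
validation.

## ROI time-course machinery

The input is an extracted ROI time series, one sample per volume (TR
1.36 s).  It is z-scored, cubic-spline interpolated onto a 20× grid and
epoched into 17-s windows (−2 to +15 s) around event onsets; edge events
without a full window are dropped and counted.  At each timepoint an OLS
GLM across events fits the registered design (standardized parametric
terms plus a constant), implemented as a single pseudoinverse
application.  The forward model for validation convolves boxcar events
(default duration 1 s) weighted by standardized term values with a
canonical double-gamma HRF (gamma shapes chosen so the response peaks at
exactly 6 s with a 16-s undershoot, ratio 6) and adds white noise on the
volume grid.

**Leave-one-out peak read-out.**  Each participant's read-out timepoint is
the peak of the absolute leave-one-out mean beta time course within 4–10 s
(absolute, because negative effects such as control updates are expected;
a flat mean falls back to the window start with a warning).  The held-out
betas at those timepoints form the group statistic (one-sample t).
Although each held-out value has mean zero under the null, the values are
cross-correlated through the shared selection, and referring the t
statistic to a t distribution rejects far above nominal level when the
null time courses contain many comparable peaks (0.17–0.42 in
simulation).  The default inference therefore compares the observed t to
a sign-flip permutation distribution — each participant's whole time
course flipped with probability 1/2 and the full LOO construction
recomputed — which is exact for sign-symmetric noise; measured null
rejection is 0.050 over 500 replicates with full power at SNR 1.  The
plain t p-value is reported alongside.

## Numerical choices and limitations

* Grid resolution bounds posterior-mean accuracy to well under the 2%
  oracle tolerance; control quantiles are linearly interpolated between
  lattice points.
* Truncation is implemented as bounded supports (the lattice itself), not
  post-hoc clipping, so all summaries respect the scales by construction.
* Degenerate designs raise with the offending terms named; participants
  with too few usable trials are skipped and logged, mirroring the
  exclusion rules.
* Problem sizes used by the test suite — a 30-agent cohort on four
  counterbalanced schedule variants, 50-seed parameter recovery, 500-null
  calibration of the LOO read-out — were chosen as the smallest cohorts at
  which the sign-level effects and calibration bands are stable.
* Real-data mode: trial tables with the documented columns can be fed to
  every analysis entry point; nothing in the pipeline assumes the data
  came from the simulator except the optional `uncertainty` column, which
  can be reconstructed with `refit_learners`.
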