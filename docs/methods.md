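# Methods

## Problem and model

`presage` estimates, prospectively and per person, how unexpected each day's
diary report is. The surprisal of observation `x_t` on day `t` is

    S(x_t) = -log P(x_t | theta_t)

where `theta_t` are the parameters of that person's predictive distribution
at that time. Variables are modeled one at a time (no joint distribution
across variables), each person separately (no pooling during updating), and
each with a family matched to its measurement type:

* **Exercise** (binary). Bernoulli likelihood, conjugate Beta prior. After
  `k` exposures in `t` days the posterior is `Beta(alpha + k, beta + t - k)`
  and the posterior predictive probability of exercise is
  `(alpha + k) / (alpha + beta + t)`.
* **Sleep duration** (hours, heaped at integers). Normal likelihood with a
  *known* observation variance and a conjugate Normal prior on the nightly
  mean. Reports heap at whole hours, so the predictive mass of a report of
  `z` hours is `Phi((z+0.5-mu_t)/sigma_t) - Phi((z-0.5-mu_t)/sigma_t)`, where
  `sigma_t^2` is the observation variance plus the remaining posterior
  variance of the mean. The support is truncated to the integers 0..24
  (nothing below zero, nothing above a full day) by renormalizing the
  half-integer bin masses over that range.
* **Stress intensity** (non-negative, zero-inflated, right-skewed). A
  hurdle-Gamma: a Bernoulli hurdle for the probability `p_zero` of reporting
  zero stress and a Gamma(shape, rate) for nonzero magnitudes, with expected
  value `E[x] = (1 - p_zero) * shape / rate`. The two-parameter Gamma has no
  conjugate prior, so the posterior over (shape, rate) is refit by sampling
  each day on all accumulated observations.

## Prior conditions

* **Uninformative**: `Beta(1, 1)` on the exercise probability;
  `Normal(7, 100)` on the mean nightly sleep (7 h center, SD 10 h);
  independent `Gamma(2, 0.1)` hyperpriors on the stress Gamma shape and
  rate, with a flat `Beta(1, 1)` hurdle.
* **Empirical (leave-one-out)**: for each target person, built from the
  other N-1 participants only. Exercise: a Beta moment-matched to the mean
  and variance of per-person exercise rates (when the variance is
  infeasible or zero, fall back to a mean-matched Beta with concentration 2
  and warn). Sleep: Normal prior mean = mean of person-level sleep means,
  prior variance = between-person sample variance of those means (floored
  at 0.25 h² so a homogeneous cohort cannot produce a delta prior), and the
  known observation variance set to the pooled within-person variance.
  Stress: Gamma hyperpriors re-centered so their means equal the
  maximum-likelihood (shape, rate) of the pooled nonzero values, with
  relative dispersion set by a coefficient of variation (default 0.5, i.e.
  `Gamma(4, 4/MLE)`); the hurdle Beta is matched to the leave-one-out zero
  rate.

The strength of the empirical priors is not separately tunable: it is
carried entirely by the between-person dispersion (moment matching) and by
the CV around the MLE, i.e. by quantities the leave-one-out sample itself
provides. Converting the stress MLEs into re-centered hyperpriors (rather
than plugging in point values) keeps the model form identical across the
two conditions.

The Gamma MLE solves the profile equation
`log(shape) - psi(shape) = log(mean x) - mean(log x)` by Newton iteration
(moment-style initialization, tolerance 1e-8, at most 100 iterations); the
rate is `shape / mean`, so the fitted mean equals the sample mean exactly.
Degenerate inputs (all values equal) make the right-hand side zero and are
rejected as errors.

## Scoring conventions

`run_prequential` walks a record in day order; missing days emit no
surprisal and trigger no update, so a complete 28-day record yields exactly
28 values. Two conventions are offered:

* **Predict-before-update** (the library default): day `t` is scored under
  the state formed from days `1..t-1`; day 1 is scored under the prior
  predictive. This is the proper one-step-ahead (prequential) score.
* **Score-after-update** (the evaluation default): day `t` is scored under
  the state that has already absorbed day `t`.

The distinction matters for the dynamic-vs-static benchmark. The static
benchmark refits the same family to the complete record by maximum
likelihood, and the per-record mean of static surprisal is therefore the
*minimum* achievable by any fixed distribution of that family — by Gibbs'
inequality the expected predict-before-update surprisal can never fall
below it, so the mean (dynamic - static) difference is non-negative in
expectation under that convention. Early negative differences — dynamic
surprisal *below* the hindsight benchmark, shrinking over time — arise only
under score-after-update, where a freshly absorbed observation raises its
own predictive mass while the posterior is still dominated by a handful of
days. Since the early-negative, attenuating pattern is precisely the
phenomenon the dynamic-vs-static comparison is designed to exhibit, the
evaluation pipeline scores after the update; the convention is a single
flag (`score_after_update`) everywhere. In both conventions the recorded
*expectation* is the forecast held before the day's report (day 1 reports
the prior-predictive mean).

## Stress sampler

The hurdle probability is conjugate and is drawn exactly from
`Beta(a0 + n_zero, b0 + n_pos)`. The (shape, rate) posterior is sampled by
adaptive random-walk Metropolis on (log shape, log rate): a spherical
Gaussian proposal whose scalar step size is adapted during warmup by
Robbins-Monro toward 30% acceptance and then frozen; the Gamma
log-likelihood is evaluated from the sufficient statistics (n, sum x,
sum log x), so each iteration is O(1). Defaults: 2000 post-warmup draws,
1000 warmup. With no positive observations the Gamma component is untouched
by data and is drawn directly from its hyperpriors. Diagnostics carry the
post-warmup acceptance rate; rates outside [0.1, 0.9] attach a warning.
Every fit seed derives deterministically from
`(base_seed, participant key, day index)` via `numpy` `SeedSequence`, so
trajectories are bit-reproducible.

Correctness is established two ways: the sampled hurdle marginal must match
its Beta closed form (within Monte-Carlo error), and simulation-based
recovery at n = 500 must return posterior means within 15% of the
generating (p_zero, shape, rate) in at least 90% of seeded replicates —
the residual failures are replicates where the data's own MLE misses by
more than 15%, i.e. sampling variability, not sampler error.

## Stress discretization

Surprisal needs a probability mass, not a density. Stress is scored on
unit-width bins (the intensity score is a sum of integer ratings): bin `j`
is centered at `j * w` and covers `((j-0.5)w, (j+0.5)w]`, except that the
first bin extends down to 0 and the last bin (default support cap 100)
absorbs the entire upper tail, so zero mass plus bin masses sum to one
exactly. Each bin's mass is the posterior mean of
`(1 - p_zero) * [F_Gamma(upper) - F_Gamma(lower)]`. Observations in a bin
whose mass underflows (below 1e-300) get a floored, finite surprisal and a
warning.

## Static benchmark and group summaries

The static reference fits the same family to the complete record: exercise
as `p_hat = k/T` clipped to `[1/(2T), 1 - 1/(2T)]` (so all-or-nothing
records keep finite surprisal); sleep as the Normal MLE (mean, variance
with the 0.25 h² floor), discretized exactly like the dynamic model; stress
as the clipped zero rate plus the Gamma MLE of the nonzero values, binned
exactly like the dynamic model. Using the same families and the same
discretizations means dynamic-minus-static differences isolate the learning
dynamics, not the distributional form.

Group summaries (expected values, surprisal, and dynamic-static
differences per day) are frequentist across participants: mean, standard
error of the mean, and mean ± 1.96 SE, deliberately ignoring each
individual value's own posterior uncertainty. Days with a single
contributing participant are reported with an undefined SE and flagged, not
dropped.

## Synthetic cohorts

The generator emulates the structure the models assume: per-person latent
parameters drawn from population distributions, then daily observations
from the person's own distribution, independently across days. Defaults
(chosen once): exercise probability `Beta(2, 6)` (population mean 0.25 —
exercise on a quarter of days); sleep person means `Normal(7, 1)` hours and
night-to-night SD 1 h, reports rounded to whole hours and clipped at 0;
stress per-person zero rate `Beta(3, 7)` (mean 0.3) with Gamma shape and
rate scattered log-normally (SD 0.3) around centers (2, 0.1), giving a mean
nonzero intensity near 20 on the 0-100+ intensity scale. Missingness, when
enabled, is completely at random per cell.

What the generator does *not* emulate — and hence what passing tests do not
show about real diaries: within-person autocorrelation (weekend effects,
stress spells), informative missingness, reporting heaping beyond whole
hours, floor/ceiling artifacts, or any dependence between the three
variables. Tests on generated cohorts validate the machinery under the
models' own assumptions, not the models' adequacy for real data.

## Numerical choices and problem sizes

Natural logarithms (nats) throughout by default; base 2 available
everywhere via `log_base`. Sleep reports are rounded half-up. Probability
normalization tolerances: 1e-9 for the discretized sleep predictive, 1e-6
for the binned stress predictive. Sequential and batch conjugate updates
agree to 1e-12. Test and example problem sizes — cohorts of 8-200
participants, 28 days, and reduced sampler draws (300-500) for day-by-day
stress refits — were chosen so the full suite completes in minutes on one
CPU while leaving every Monte-Carlo assertion at 3 or more standard errors
of slack.

## Known limitations

* The sleep observation variance is treated as known (default 2.25 h²;
  pooled within-person variance in the empirical condition) rather than
  inferred; a Normal-Inverse-Gamma extension would relax this.
* "Hierarchical" here means the hurdle's two-part structure within a
  person; there is no partial pooling across people during updating.
* The random-walk sampler is adequate for the 2-parameter Gamma posterior
  but mixes more slowly than gradient-based samplers would on larger
  models.
* Daily refitting is O(T) posterior fits per participant per condition;
  with default draw counts a 100-person, 28-day stress analysis is minutes
  of compute, not seconds.
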