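# presage

Prospective Bayesian surprisal estimation for daily-diary exposure
variables.

In daily-diary (ecological momentary assessment) studies of migraine, how
*unexpected* a trigger exposure is — its surprisal,
`S(x_t) = -log P(x_t | theta_t)` — predicts near-term headache risk better
than the exposure itself. But classical surprisal needs a well-sampled
empirical distribution, formed only after weeks of observation. `presage`
estimates surprisal *prospectively*: expectations are updated day by day
with Bayesian models suited to each measurement type, so surprisal is
available from day 1, under conditions of limited personal data.

Three variable types are covered, each with its own sequential model:

| variable | measurement type | model |
|---|---|---|
| exercise | binary (yes/no) | Bernoulli with conjugate Beta prior; predictive `(alpha+k)/(alpha+beta+t)` |
| sleep | hours, heaped at integers | Normal with known variance, conjugate prior on the mean; predictive mass between half-integer bounds, truncated to 0-24 h |
| stress | non-negative, zero-inflated, skewed | hurdle-Gamma; conjugate Beta hurdle + (shape, rate) posterior resampled daily |

Two prior regimes are supported — **uninformative** (flat Beta(1,1);
Normal(7, 100) on mean sleep; Gamma(2, 0.1) hyperpriors on the stress shape
and rate) and **empirical leave-one-out** (moment-matched to the other N-1
participants) — and prospective trajectories are benchmarked against
**static empirical surprisal**, the hindsight score under a distribution
fitted to each person's complete record. See `docs/methods.md` for the full
model account.

The package is aimed at headache/EMA researchers and methodologists working
on real-time forecasting from sparse personal data streams.

## Worked example

`examples/` contains one narrative script per capability. The flagship
comparison (`examples/04_prior_conditions_vs_static.py`) simulates a
200-person, 28-day cohort, runs the exercise model under both prior
conditions, and compares prospective surprisal to the hindsight benchmark:

```text
mean (dynamic - static) exercise surprisal, nats, with 95% CI
cond            day   mean      95% CI            n
uninformative     1  -0.110  [-0.184, -0.037]  200
uninformative     2  -0.096  [-0.165, -0.027]  200
uninformative     7  -0.055  [-0.099, -0.010]  200
uninformative    14  +0.002  [-0.026, +0.029]  200
uninformative    28  +0.004  [-0.005, +0.013]  200
empirical         1  -0.044  [-0.089, -0.000]  200
empirical         2  -0.056  [-0.102, -0.011]  200
empirical         7  -0.027  [-0.064, +0.010]  200
empirical        14  +0.005  [-0.020, +0.030]  200
empirical        28  +0.007  [-0.006, +0.019]  200

uninformative: week-1 mean -0.0558 -> week-4 mean +0.0063
empirical: week-1 mean -0.0311 -> week-4 mean +0.0101
```

Early in the record, prospective surprisal sits *below* the
full-information benchmark (negative differences), more so under the
uninformative prior; both conditions attenuate toward zero by week 4 as
individual learning catches up with hindsight. The other examples print a
single person's day-by-day exercise updating from the flat prior
(expectation starts at exactly 0.5), a week of sleep reports sharpening the
discretized Normal predictive, and 28 daily hurdle-Gamma refits recovering
a person's stress parameters.

A minimal library session:

```python
from presage import BetaBernoulliState, run_prequential

traj = run_prequential([1, 0, 0, 1], BetaBernoulliState(alpha=1, beta=1))
traj.surprisal   # array([0.693, 1.099, 0.693, 0.916]) — nats per day
```

## Command line

```sh
presage simulate --config cfg.yaml --out outdir   # write a synthetic diary CSV
presage run      --config cfg.yaml --out outdir   # trajectories + summaries
presage compare  --out outdir                     # re-derive the difference table
```

The run writes tidy CSVs (`trajectories.csv`, `static.csv`,
`expectations_by_day.csv`, `surprisal_by_day.csv`, `difference_by_day.csv`)
plus a JSON manifest with the seed and config hash; reruns with the same
config are bit-identical.

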