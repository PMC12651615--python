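"""Daily hurdle-Gamma refits for zero-inflated, right-skewed stress scores.

Stress intensity is modeled as a point mass at zero (the hurdle) plus a
Gamma distribution for nonzero days.  The Gamma shape/rate have no conjugate
prior, so the posterior is re-sampled each day on all accumulated
observations; the hurdle probability itself is updated in closed form.
"""

import warnings

import numpy as np

from presage import HurdleGammaModel, HurdleGammaPrior, run_prequential

rng = np.random.default_rng(11)
true_p_zero, true_shape, true_rate = 0.3, 2.0, 0.1  # mean nonzero stress 20
obs = np.where(rng.random(28) < true_p_zero, 0.0,
               rng.gamma(true_shape, 1 / true_rate, 28))

model = HurdleGammaModel(HurdleGammaPrior(), n_draws=500, n_warmup=500, base_seed=1)
with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    traj = run_prequential(obs, model)

print("day  stress  P(bin)   surprisal  E[stress]")
for i, d in enumerate(traj.day):
    print(f"{d:3d}  {obs[i]:6.1f}  {traj.p_obs[i]:7.4f}  {traj.surprisal[i]:9.3f}"
          f"  {traj.expectation[i]:9.2f}")

post = traj.final_state.posterior()
print(f"\nposterior means after 28 days: p_zero={post.p_zero.mean():.3f} "
      f"(true {true_p_zero}), shape={post.shape.mean():.2f} (true {true_shape}), "
      f"rate={post.rate.mean():.3f} (true {true_rate})")
print("\nZero days are scored by the hurdle mass; positive days by the")
print("unit-width Gamma bin containing the report. The day-1 forecast")
print("E[stress] reflects only the weakly informative hyperpriors (about 1)")
print("and badly undershoots this person's true mean of 14; it climbs")
print("toward the truth within the first two weeks of observations.")
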