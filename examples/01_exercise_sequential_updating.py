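"""Sequential Beta-Bernoulli updating and surprisal for a binary exposure.

Simulates one person who exercises on about a quarter of days, then scores
each day's report under the flat Beta(1, 1) prior: the predictive starts at
0.5 and is pulled toward the person's own rate as evidence accumulates, so
exercise days (the rarer event) stay surprising while rest days become
routine.
"""

import numpy as np

from presage import BetaBernoulliState, run_prequential

rng = np.random.default_rng(7)
obs = rng.binomial(1, 0.25, size=28)

traj = run_prequential(obs, BetaBernoulliState(alpha=1, beta=1))

print("day  obs  P(obs)  surprisal(nats)  E[exercise tomorrow]")
for d, x in zip(traj.day, obs):
    i = d - 1
    print(f"{d:3d}  {x:3d}  {traj.p_obs[i]:6.3f}  {traj.surprisal[i]:15.3f}"
          f"  {traj.expectation[i]:20.3f}")

final = traj.final_state
print(f"\nfinal counts: k={final.k} exercise days in t={final.t} days")
print(f"final predictive: {final.predictive():.3f} "
      f"(true rate used by the simulation: 0.25)")
print("\nThe expectation column is the forecast held *before* each day's")
print("report; day 1 is the prior predictive 0.5. Surprisal is -ln P(obs):")
print("high when the day contradicts the running expectation.")
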