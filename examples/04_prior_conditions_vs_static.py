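"""Dynamic-vs-static surprisal under uninformative and empirical priors.

Simulates a 200-person diary cohort, runs the exercise model under both
prior conditions, and compares the prospective (dynamic) surprisal of each
day to the hindsight benchmark fitted to each person's complete record.
Early on, dynamic surprisal sits below the benchmark — the freshly updated
posterior overweights the few observations it has seen — and the gap is
larger and noisier when starting from the flat prior than from the
leave-one-out empirical prior.
"""

from presage import CohortConfig, RunConfig, run_pipeline

cfg = RunConfig(
    simulate=CohortConfig(n_participants=200, n_days=28, seed=0),
    variables=("exercise",),
    base_seed=0,
)
diff = run_pipeline(cfg)["difference_by_day"]

print("mean (dynamic - static) exercise surprisal, nats, with 95% CI")
print("cond            day   mean      95% CI            n")
for cond in ("uninformative", "empirical"):
    d = diff[diff["prior_condition"] == cond].set_index("day")
    for day in (1, 2, 7, 14, 28):
        row = d.loc[day]
        print(f"{cond:14s}  {day:3d}  {row['estimate']:+.3f}  "
              f"[{row['ci_lo']:+.3f}, {row['ci_hi']:+.3f}]  {int(row['n'])}")

for cond in ("uninformative", "empirical"):
    d = diff[diff["prior_condition"] == cond]
    w1 = d[d["day"] <= 7]["estimate"].mean()
    w4 = d[d["day"] >= 22]["estimate"].mean()
    print(f"\n{cond}: week-1 mean {w1:+.4f} -> week-4 mean {w4:+.4f}")

print("\nNegative values mean prospective surprisal under-shoots the")
print("full-information benchmark; both conditions converge toward zero")
print("as individual learning catches up with hindsight.")
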