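"""Synthetic diary-cohort generator.

Emulates the statistical structure the sequential models assume: a cohort of
participants each observed for 28 days, with per-person latent parameters
drawn from population distributions and daily observations drawn from the
person's own distribution —

* exercise: per-person probability ``p ~ Beta`` (population mean 0.25, i.e.
  exercise on a quarter of days), daily indicator ``Bernoulli(p)``;
* sleep: per-person nightly mean ``mu ~ Normal(7, between_sd^2)`` hours,
  nightly report ``round(max(0, Normal(mu, within_sd)))`` — integer-heaped
  like real self-reports;
* stress: per-person zero-report probability ``~ Beta`` and Gamma
  (shape, rate) scattered log-normally around population centers; daily
  value is 0 with the hurdle probability, else a Gamma draw.

Missingness, when enabled, is independent per cell (MCAR).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["CohortConfig", "simulate_cohort"]


@dataclass
class CohortConfig:
    """Population-level parameters of a simulated diary cohort."""

    n_participants: int = 100
    n_days: int = 28
    seed: int = 0
    # exercise: population Beta on per-person daily exercise probability
    exercise_alpha: float = 2.0
    exercise_beta: float = 6.0
    # sleep (hours)
    sleep_mean: float = 7.0
    sleep_between_sd: float = 1.0
    sleep_within_sd: float = 1.0
    # stress: population Beta on per-person zero rate; lognormal dispersion
    # of per-person Gamma shape/rate around the centers
    stress_zero_alpha: float = 3.0
    stress_zero_beta: float = 7.0
    stress_shape_center: float = 2.0
    stress_rate_center: float = 0.1
    stress_log_sd: float = 0.3
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_participants < 0 or self.n_days < 0:
            raise ValueError("cohort dimensions must be non-negative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        positives = (
            self.exercise_alpha,
            self.exercise_beta,
            self.sleep_between_sd,
            self.sleep_within_sd,
            self.stress_zero_alpha,
            self.stress_zero_beta,
            self.stress_shape_center,
            self.stress_rate_center,
        )
        if any(v <= 0 for v in positives):
            raise ValueError("population parameters must be positive")
        if self.stress_log_sd < 0:
            raise ValueError("stress_log_sd must be non-negative")


def simulate_cohort(
    config: Optional[CohortConfig] = None, *, return_truth: bool = False
):
    """Generate a diary dataset (and optionally the latent person truth).

    Returns a long-format DataFrame with one row per participant-day and
    columns ``participant_id, day, stress, sleep_hours, exercise``; missing
    cells are NaN.  With ``return_truth=True`` also returns a per-person
    DataFrame of the latent parameters, useful for recovery studies.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    n, T = config.n_participants, config.n_days

    ids = [f"P{i + 1:04d}" for i in range(n)]
    p_exercise = rng.beta(config.exercise_alpha, config.exercise_beta, size=n)
    sleep_mu = rng.normal(config.sleep_mean, config.sleep_between_sd, size=n)
    p_zero = rng.beta(config.stress_zero_alpha, config.stress_zero_beta, size=n)
    shape = config.stress_shape_center * rng.lognormal(0.0, config.stress_log_sd, size=n)
    rate = config.stress_rate_center * rng.lognormal(0.0, config.stress_log_sd, size=n)

    rows = []
    for i in range(n):
        exercise = rng.binomial(1, p_exercise[i], size=T).astype(float)
        sleep = np.round(np.clip(rng.normal(sleep_mu[i], config.sleep_within_sd, size=T), 0, None))
        is_zero = rng.random(T) < p_zero[i]
        stress = np.where(is_zero, 0.0, rng.gamma(shape[i], 1.0 / rate[i], size=T))
        frame = pd.DataFrame(
            {
                "participant_id": ids[i],
                "day": np.arange(1, T + 1),
                "stress": stress,
                "sleep_hours": sleep,
                "exercise": exercise,
            }
        )
        rows.append(frame)

    if rows:
        data = pd.concat(rows, ignore_index=True)
    else:
        data = pd.DataFrame(
            columns=["participant_id", "day", "stress", "sleep_hours", "exercise"]
        )

    if config.missing_rate > 0 and len(data):
        for col in ("stress", "sleep_hours", "exercise"):
            mask = rng.random(len(data)) < config.missing_rate
            data.loc[mask, col] = np.nan

    if return_truth:
        truth = pd.DataFrame(
            {
                "participant_id": ids,
                "p_exercise": p_exercise,
                "sleep_mu": sleep_mu,
                "stress_p_zero": p_zero,
                "stress_shape": shape,
                "stress_rate": rate,
            }
        )
        return data, truth
    return data
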