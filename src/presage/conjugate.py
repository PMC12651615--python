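"""Closed-form conjugate sequential models for binary and heaped data.

Two of the three diary variables admit exact conjugate updating:

* **Exercise** (daily yes/no) — Bernoulli likelihood with a Beta prior.
  After ``k`` exposures in ``t`` days the posterior is
  ``Beta(alpha + k, beta + t - k)`` and the posterior predictive probability
  of exercising tomorrow is ``(alpha + k) / (alpha + beta + t)``.
* **Sleep duration** (hours, heaped at whole numbers) — Normal likelihood
  with known observation variance and a conjugate Normal prior on the mean.
  Self-reports round to the nearest hour, so the predictive probability of a
  report of ``z`` hours is the Normal mass between the half-integer bounds
  ``z - 0.5`` and ``z + 0.5``, truncated to the physical support 0..24 h and
  renormalized.

Both model states are immutable; ``update`` returns a new state so
trajectories can be replayed and compared safely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Any, Iterable

import numpy as np
from scipy.stats import norm

from .surprisal import safe_surprisal

__all__ = [
    "BetaBernoulliState",
    "NormalMeanState",
    "DiscretizedPredictive",
    "discretize_normal",
    "sleep_surprisal",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero-ward up.

    Matches the half-integer bin edges of the discretized sleep predictive:
    8.5 h falls in the bin centered at 9.
    """
    return int(math.floor(float(x) + 0.5))


@dataclass(frozen=True)
class BetaBernoulliState:
    """Beta prior plus Bernoulli counts for a binary daily exposure.

    The prior hyperparameters ``(alpha, beta)`` and the accumulated counts
    ``(k, t)`` — exposures observed and days observed — are carried
    separately, so the posterior is always ``Beta(alpha + k, beta + t - k)``.
    """

    alpha: float
    beta: float
    k: int = 0
    t: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta hyperparameters must be positive")
        if not (0 <= self.k <= self.t):
            raise ValueError(f"counts must satisfy 0 <= k <= t, got k={self.k}, t={self.t}")

    @property
    def day_index(self) -> int:
        return self.t

    def posterior(self) -> tuple[float, float]:
        """Posterior Beta parameters ``(alpha + k, beta + t - k)``."""
        return (self.alpha + self.k, self.beta + self.t - self.k)

    def predictive(self) -> float:
        """Posterior predictive probability of an exposure tomorrow."""
        return (self.alpha + self.k) / (self.alpha + self.beta + self.t)

    def predictive_mass(self, x: Any) -> float:
        x = _as_binary(x)
        p = self.predictive()
        return p if x == 1 else 1.0 - p

    def expectation(self) -> float:
        return self.predictive()

    def update(self, x: Any) -> "BetaBernoulliState":
        x = _as_binary(x)
        return replace(self, k=self.k + x, t=self.t + 1)

    def absorb(self, xs: Iterable[Any]) -> "BetaBernoulliState":
        """Batch update with a sequence of observations."""
        state = self
        for x in xs:
            state = state.update(x)
        return state


def _as_binary(x: Any) -> int:
    xf = float(x)
    if xf not in (0.0, 1.0):
        raise ValueError(f"binary observation must be 0 or 1, got {x!r}")
    return int(xf)


@dataclass(frozen=True)
class DiscretizedPredictive:
    """Probability mass over integer hours after truncation renormalization."""

    support: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        total = float(np.sum(self.mass))
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"discretized mass sums to {total}, not 1")

    def mass_at(self, z: int) -> float:
        z = int(z)
        lo = int(self.support[0])
        hi = int(self.support[-1])
        if not (lo <= z <= hi):
            return 0.0
        return float(self.mass[z - lo])

    def mean(self) -> float:
        return float(np.sum(self.support * self.mass))


def discretize_normal(
    mu: float, sigma: float, z_min: int = 0, z_max: int = 24
) -> DiscretizedPredictive:
    """Half-integer-bin discretization of a Normal predictive.

    The mass at integer ``z`` is proportional to
    ``Phi((z + 0.5 - mu)/sigma) - Phi((z - 0.5 - mu)/sigma)`` and the masses
    are renormalized over ``[z_min, z_max]`` — truncation is implemented by
    renormalization, so mass outside the support (including below
    ``z_min - 0.5``) is discarded rather than folded into the edge bins.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if z_min > z_max:
        raise ValueError(f"z_min={z_min} exceeds z_max={z_max}")
    support = np.arange(int(z_min), int(z_max) + 1)
    upper = norm.cdf((support + 0.5 - mu) / sigma)
    lower = norm.cdf((support - 0.5 - mu) / sigma)
    raw = upper - lower
    total = raw.sum()
    if total <= 0:
        # Predictive concentrated entirely outside the support; fall back to
        # the nearest edge bin rather than dividing by zero.
        raw = np.zeros_like(raw)
        raw[0 if mu < z_min else -1] = 1.0
        total = 1.0
    return DiscretizedPredictive(support=support, mass=raw / total)


@dataclass(frozen=True)
class NormalMeanState:
    """Known-variance Normal model with a conjugate Normal prior on the mean.

    Parameters
    ----------
    mu_prior, var_prior
        Prior mean and variance of the latent nightly sleep mean (hours,
        hours squared).
    obs_var
        Known night-to-night observation variance (hours squared).  The
        default 2.25 corresponds to an SD of 1.5 h; the empirical-prior
        condition replaces it with the pooled within-person variance.
    n, sum_obs
        Sufficient statistics of the absorbed observations.
    z_min, z_max
        Integer support of the discretized predictive (0..24 h).
    """

    mu_prior: float
    var_prior: float
    obs_var: float = 2.25
    n: int = 0
    sum_obs: float = 0.0
    z_min: int = 0
    z_max: int = 24

    def __post_init__(self) -> None:
        if self.var_prior <= 0 or self.obs_var <= 0:
            raise ValueError("variances must be positive")
        if self.n < 0:
            raise ValueError("n must be non-negative")

    @property
    def day_index(self) -> int:
        return self.n

    @property
    def posterior_mean(self) -> float:
        """Precision-weighted blend of the prior mean and the sample mean."""
        prec = 1.0 / self.var_prior + self.n / self.obs_var
        return (self.mu_prior / self.var_prior + self.sum_obs / self.obs_var) / prec

    @property
    def posterior_var(self) -> float:
        return 1.0 / (1.0 / self.var_prior + self.n / self.obs_var)

    @property
    def predictive_sd(self) -> float:
        """SD of the predictive for a new night: observation noise plus
        remaining uncertainty about the mean."""
        return math.sqrt(self.obs_var + self.posterior_var)

    def update(self, x: float) -> "NormalMeanState":
        x = float(x)
        if x < 0:
            raise ValueError(f"sleep duration must be non-negative, got {x}")
        return replace(self, n=self.n + 1, sum_obs=self.sum_obs + x)

    def absorb(self, xs: Iterable[float]) -> "NormalMeanState":
        state = self
        for x in xs:
            state = state.update(x)
        return state

    def discretized(self) -> DiscretizedPredictive:
        return discretize_normal(
            self.posterior_mean, self.predictive_sd, self.z_min, self.z_max
        )

    def predictive_mass(self, x: float) -> float:
        if float(x) < 0:
            raise ValueError(f"sleep duration must be non-negative, got {x}")
        z = round_half_up(x)
        z = min(max(z, self.z_min), self.z_max)
        return self.discretized().mass_at(z)

    def expectation(self) -> float:
        return self.discretized().mean()


def sleep_surprisal(obs_hours: float, state: NormalMeanState, log_base: Any = "e") -> float:
    """Surprisal of a sleep report, rounded to the nearest hour first."""
    return safe_surprisal(state.predictive_mass(obs_hours), log_base)
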