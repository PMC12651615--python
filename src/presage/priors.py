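"""Prior construction: uninformative and leave-one-out empirical conditions.

Two prior regimes are compared throughout the package:

* **Uninformative** — minimal-knowledge constants: a flat Beta(1, 1) on the
  exercise probability, a diffuse Normal(7, 100) on the mean nightly sleep
  (SD 10 h around a 7 h center), and weakly informative Gamma(2, 0.1)
  hyperpriors on the stress Gamma shape and rate.
* **Empirical (leave-one-out)** — for each target participant, a prior built
  from the other N-1 participants only: moment-matched Beta from the spread
  of per-person exercise rates, a Normal on the sleep mean centered on the
  between-person mean of person means with the between-person variance, and
  stress hyperpriors re-centered on the Gamma maximum-likelihood fit to the
  pooled nonzero stress values.

The Gamma MLE is solved by Newton iteration on the digamma equation
``log(shape) - psi(shape) = log(mean(x)) - mean(log x)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Any, Sequence, Union

import numpy as np
from scipy.special import digamma, polygamma

from .conjugate import BetaBernoulliState, NormalMeanState
from .stress import HurdleGammaPrior

__all__ = [
    "PriorSpec",
    "VARIABLES",
    "uninformative_prior",
    "beta_from_moments",
    "empirical_prior_exercise",
    "empirical_prior_sleep",
    "empirical_prior_stress",
    "gamma_mle",
]

VARIABLES = ("exercise", "sleep", "stress")

#: Floor on the between-person sleep variance; prevents a delta-function
#: prior when every person in the leave-one-out sample has the same mean.
SLEEP_VAR_FLOOR = 0.25


@dataclass(frozen=True)
class PriorSpec:
    """A prior condition for one variable.

    ``parameters`` is the model-specific prior block: a
    :class:`~presage.conjugate.BetaBernoulliState` with zero counts for
    exercise, a :class:`~presage.conjugate.NormalMeanState` with ``n = 0``
    for sleep, or a :class:`~presage.stress.HurdleGammaPrior` for stress.
    """

    condition: str
    variable: str
    parameters: Any

    def __post_init__(self) -> None:
        if self.condition not in ("uninformative", "empirical"):
            raise ValueError(f"unknown prior condition {self.condition!r}")
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")


def uninformative_prior(variable: str, *, sleep_obs_var: float = 2.25) -> PriorSpec:
    """The minimal-knowledge prior for one variable.

    exercise -> Beta(1, 1); sleep -> Normal(7, 100) on the mean (with the
    configurable known observation variance); stress -> Gamma(2, 0.1)
    hyperpriors on shape and rate with a flat Beta(1, 1) hurdle.
    """
    if variable == "exercise":
        params: Any = BetaBernoulliState(alpha=1.0, beta=1.0)
    elif variable == "sleep":
        params = NormalMeanState(mu_prior=7.0, var_prior=100.0, obs_var=sleep_obs_var)
    elif variable == "stress":
        params = HurdleGammaPrior(
            hurdle_alpha=1.0,
            hurdle_beta=1.0,
            shape_prior=(2.0, 0.1),
            rate_prior=(2.0, 0.1),
        )
    else:
        raise ValueError(f"unknown variable {variable!r}")
    return PriorSpec(condition="uninformative", variable=variable, parameters=params)


def beta_from_moments(
    m: float, v: float, fallback_concentration: float = 2.0
) -> tuple[float, float]:
    """Beta(alpha, beta) with mean ``m`` and variance ``v``.

    Moment inversion requires ``0 < v < m(1 - m)``; otherwise (degenerate or
    over-dispersed inputs) fall back to a mean-matched Beta at the fallback
    concentration and warn.
    """
    if not (0.0 < m < 1.0):
        raise ValueError(f"mean must lie strictly in (0, 1), got {m}")
    feasible_var = m * (1.0 - m)
    if v <= 0 or v >= feasible_var:
        warnings.warn(
            f"moment matching infeasible (mean={m:.4g}, var={v:.4g}); "
            f"falling back to mean-matched Beta with concentration "
            f"{fallback_concentration}",
            RuntimeWarning,
            stacklevel=2,
        )
        nu = fallback_concentration
    else:
        nu = feasible_var / v - 1.0
    return (m * nu, (1.0 - m) * nu)


def empirical_prior_exercise(loo_person_rates: Sequence[float]) -> PriorSpec:
    """Moment-matched Beta prior from leave-one-out per-person exercise rates."""
    rates = np.asarray(list(loo_person_rates), dtype=float)
    if rates.size < 2:
        raise ValueError("need at least two leave-one-out participants")
    if np.any((rates < 0) | (rates > 1)):
        raise ValueError("exercise rates must lie in [0, 1]")
    m = float(rates.mean())
    v = float(rates.var(ddof=1))
    m = min(max(m, 1e-6), 1.0 - 1e-6)
    alpha, beta = beta_from_moments(m, v)
    return PriorSpec(
        condition="empirical",
        variable="exercise",
        parameters=BetaBernoulliState(alpha=alpha, beta=beta),
    )


def empirical_prior_sleep(
    loo_records: Sequence[Sequence[float]],
    *,
    var_floor: float = SLEEP_VAR_FLOOR,
    default_obs_var: float = 2.25,
) -> PriorSpec:
    """Normal prior on the sleep mean from leave-one-out records.

    Prior mean = mean of the person-level sleep means; prior variance =
    between-person (sample) variance of those means, floored at
    ``var_floor``; the known observation variance is the pooled
    within-person variance of the leave-one-out sample.
    """
    records = [np.asarray([v for v in r if not np.isnan(v)], dtype=float) for r in loo_records]
    records = [r for r in records if r.size > 0]
    if len(records) < 2:
        raise ValueError(
            "between-person variance undefined: need at least two "
            "leave-one-out participants with sleep data"
        )
    means = np.array([r.mean() for r in records])
    prior_mean = float(means.mean())
    prior_var = float(means.var(ddof=1))
    if prior_var < var_floor:
        prior_var = var_floor
    ss = sum(float(((r - r.mean()) ** 2).sum()) for r in records if r.size > 1)
    dof = sum(r.size - 1 for r in records if r.size > 1)
    if dof > 0 and ss > 0:
        obs_var = ss / dof
    else:
        warnings.warn(
            "pooled within-person variance undefined or zero; using default "
            f"observation variance {default_obs_var}",
            RuntimeWarning,
            stacklevel=2,
        )
        obs_var = default_obs_var
    return PriorSpec(
        condition="empirical",
        variable="sleep",
        parameters=NormalMeanState(
            mu_prior=prior_mean, var_prior=prior_var, obs_var=obs_var
        ),
    )


def gamma_mle(
    values: Sequence[float], *, tol: float = 1e-8, max_iter: int = 100
) -> tuple[float, float]:
    """Maximum-likelihood (shape, rate) of a Gamma distribution.

    Newton iteration on the profile equation
    ``log(shape) - psi(shape) = log(mean) - mean(log x)`` with the standard
    moment-style initialization; the rate follows as ``shape / mean``, so at
    the optimum the fitted mean equals the sample mean exactly.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("Gamma MLE requires at least two values")
    if np.any(x <= 0):
        raise ValueError("Gamma MLE requires strictly positive values")
    mean = float(x.mean())
    s = math.log(mean) - float(np.log(x).mean())
    if s <= 0:
        raise ValueError("degenerate data: all values (numerically) equal")
    shape = (3.0 - s + math.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(max_iter):
        f = math.log(shape) - float(digamma(shape)) - s
        fprime = 1.0 / shape - float(polygamma(1, shape))
        step = f / fprime
        new_shape = shape - step
        if new_shape <= 0:
            new_shape = shape / 2.0
        if abs(new_shape - shape) < tol * max(1.0, shape):
            shape = new_shape
            break
        shape = new_shape
    else:
        raise RuntimeError(f"Gamma MLE did not converge in {max_iter} iterations")
    return (shape, shape / mean)


def empirical_prior_stress(
    loo_nonzero_values: Sequence[float],
    loo_zero_rate: Union[float, Sequence[float]],
    *,
    cv: float = 0.5,
) -> PriorSpec:
    """Hurdle-Gamma prior re-centered on leave-one-out MLEs.

    The Gamma hyperpriors keep the Gamma(a, b) form but are re-centered so
    their means equal the pooled-nonzero MLEs, with relative dispersion set
    by the coefficient of variation ``cv`` (a = 1/cv^2, b = a/MLE).  The
    hurdle Beta is matched to the leave-one-out zero rate: full moment
    matching when per-person rates are given, mean matching at concentration
    2 for a scalar pooled rate.
    """
    vals = np.asarray(list(loo_nonzero_values), dtype=float)
    if vals.size < 10:
        raise ValueError("need at least 10 nonzero stress values")
    if cv <= 0:
        raise ValueError("cv must be positive")
    shape_mle, rate_mle = gamma_mle(vals)
    a = 1.0 / cv**2
    shape_prior = (a, a / shape_mle)
    rate_prior = (a, a / rate_mle)

    zr = np.atleast_1d(np.asarray(loo_zero_rate, dtype=float))
    if np.any((zr < 0) | (zr > 1)):
        raise ValueError("zero rates must lie in [0, 1]")
    m = float(np.clip(zr.mean(), 1e-6, 1.0 - 1e-6))
    if zr.size >= 2:
        hurdle_alpha, hurdle_beta = beta_from_moments(m, float(zr.var(ddof=1)))
    else:
        hurdle_alpha, hurdle_beta = (2.0 * m, 2.0 * (1.0 - m))
    return PriorSpec(
        condition="empirical",
        variable="stress",
        parameters=HurdleGammaPrior(
            hurdle_alpha=hurdle_alpha,
            hurdle_beta=hurdle_beta,
            shape_prior=shape_prior,
            rate_prior=rate_prior,
        ),
    )
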