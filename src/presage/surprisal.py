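"""Self-information (surprisal) and one-step-ahead sequential scoring.

The surprisal of an observation ``x`` under a predictive distribution with
probability mass ``P(x)`` is ``S(x) = -log P(x)``: certain events carry no
information, improbable events carry a lot.  Surprisal is measured in nats
(natural log, the default) or bits (base 2).

:func:`run_prequential` walks a diary record day by day, scoring each
observation against the predictive distribution and then absorbing it into
the model state, producing one surprisal value per non-missing day.  Two
scoring conventions are supported:

* ``score_after_update=False`` (default): classic prequential / one-step-ahead
  scoring — day ``t`` is scored under the state formed from days ``1..t-1``,
  so day 1 is scored under the prior predictive.
* ``score_after_update=True``: day ``t`` is scored under the state that has
  already absorbed day ``t``.  Early in a record the observation raises its
  own predictive mass, which biases surprisal downward relative to a
  hindsight benchmark; this is the convention used by the dynamic-vs-static
  evaluation (see :mod:`presage.evaluation` and docs/methods.md).

Both conventions emit exactly one value per observation; a complete 28-day
record yields a 28-point trajectory.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Optional, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

__all__ = [
    "surprisal",
    "safe_surprisal",
    "MAX_SURPRISAL_MASS",
    "PredictiveModel",
    "SurprisalTrajectory",
    "run_prequential",
]

#: Probability-mass floor used by :func:`safe_surprisal`; masses below this
#: are treated as numerically indistinguishable from zero.
MAX_SURPRISAL_MASS = 1e-300


def _log_scale(log_base: Any) -> float:
    """Return the divisor converting natural log to the requested base."""
    if log_base in ("e", math.e, None):
        return 1.0
    if log_base in ("2", 2, 2.0):
        return math.log(2.0)
    raise ValueError(f"log_base must be 'e' or 2, got {log_base!r}")


def surprisal(p: float, log_base: Any = "e") -> float:
    """Surprisal ``-log(p)`` of an event with probability mass ``p``.

    Parameters
    ----------
    p
        Probability mass of the observed event; must lie in ``(0, 1]``.
        A zero or negative value signals an invalid mass (for example an
        unclipped empirical zero) and raises rather than returning ``inf``.
    log_base
        ``"e"`` for nats (default) or ``2`` for bits.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(
            f"surprisal requires a probability mass in (0, 1], got {p!r}"
        )
    return -math.log(p) / _log_scale(log_base)


def safe_surprisal(p: float, log_base: Any = "e") -> float:
    """Like :func:`surprisal` but overflow-safe for vanishing masses.

    Masses below :data:`MAX_SURPRISAL_MASS` (or exactly zero) are floored
    there, a warning is emitted, and the corresponding large-but-finite
    surprisal is returned.  Used when scoring observations that fall in the
    far tail of a discretized predictive.
    """
    if p > 1.0:
        raise ValueError(f"probability mass exceeds 1: {p!r}")
    if p < MAX_SURPRISAL_MASS:
        warnings.warn(
            f"predictive mass {p!r} underflowed; surprisal floored at "
            f"-log({MAX_SURPRISAL_MASS})",
            RuntimeWarning,
            stacklevel=2,
        )
        p = MAX_SURPRISAL_MASS
    return -math.log(p) / _log_scale(log_base)


@runtime_checkable
class PredictiveModel(Protocol):
    """Contract every sequential predictive model satisfies.

    A model is an immutable snapshot of belief: ``update`` returns a new
    model and never mutates, ``day_index`` counts the observations absorbed,
    ``predictive_mass`` evaluates the probability mass the one-step-ahead
    predictive assigns to a value, and ``expectation`` is the predictive mean.
    The masses over the model's declared support must sum to one.
    """

    @property
    def day_index(self) -> int:  # pragma: no cover - protocol stub
        ...

    def predictive_mass(self, x: float) -> float:  # pragma: no cover
        ...

    def update(self, x: float) -> "PredictiveModel":  # pragma: no cover
        ...

    def expectation(self) -> float:  # pragma: no cover
        ...


def _is_missing(x: Any) -> bool:
    if x is None:
        return True
    try:
        return bool(np.isnan(x))
    except TypeError:
        return False


@dataclass
class SurprisalTrajectory:
    """Per-day surprisal record for one participant x variable x prior.

    Attributes
    ----------
    day
        Day indices (1-based) of the scored, non-missing observations.
    p_obs
        Predictive mass assigned to each scored observation.
    surprisal
        ``-log p_obs`` in the requested base.
    expectation
        Predictive mean held *before* the day's update (the day's forecast);
        day 1 therefore reports the prior-predictive mean regardless of the
        scoring convention.
    final_state
        Model state after absorbing every non-missing observation.
    """

    day: np.ndarray
    p_obs: np.ndarray
    surprisal: np.ndarray
    expectation: np.ndarray
    final_state: Any
    log_base: Any = "e"
    score_after_update: bool = False

    def __len__(self) -> int:
        return len(self.day)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.day,
                "p_obs": self.p_obs,
                "surprisal": self.surprisal,
                "expectation": self.expectation,
            }
        )


def run_prequential(
    observations: Sequence[Any],
    initial_state: PredictiveModel,
    *,
    days: Optional[Sequence[int]] = None,
    score_after_update: bool = False,
    log_base: Any = "e",
) -> SurprisalTrajectory:
    """Score a day-ordered record sequentially and return its trajectory.

    Parameters
    ----------
    observations
        Day-ordered values; ``None``/``NaN`` mark missing days, which emit no
        surprisal and trigger no update.
    initial_state
        A prior-state model (``day_index == 0``) obeying the
        :class:`PredictiveModel` contract.
    days
        Optional explicit day indices (strictly increasing); defaults to
        ``1..len(observations)``.
    score_after_update
        Scoring convention; see the module docstring.

    Returns
    -------
    SurprisalTrajectory
        One entry per non-missing day, in order.
    """
    if initial_state.day_index != 0:
        raise ValueError(
            "initial_state must be a prior state with day_index == 0, "
            f"got day_index={initial_state.day_index}"
        )
    if days is None:
        day_idx = list(range(1, len(observations) + 1))
    else:
        day_idx = [int(d) for d in days]
        if len(day_idx) != len(observations):
            raise ValueError("days and observations must have equal length")
        if any(b <= a for a, b in zip(day_idx, day_idx[1:])):
            raise ValueError("day indices must be strictly increasing")

    state = initial_state
    out_day: list[int] = []
    out_p: list[float] = []
    out_s: list[float] = []
    out_e: list[float] = []
    for d, x in zip(day_idx, observations):
        if _is_missing(x):
            continue
        forecast_mean = state.expectation()
        p_before = state.predictive_mass(x)
        new_state = state.update(x)
        p_score = new_state.predictive_mass(x) if score_after_update else p_before
        out_day.append(d)
        out_p.append(p_score)
        out_s.append(safe_surprisal(p_score, log_base))
        out_e.append(forecast_mean)
        state = new_state

    return SurprisalTrajectory(
        day=np.asarray(out_day, dtype=int),
        p_obs=np.asarray(out_p, dtype=float),
        surprisal=np.asarray(out_s, dtype=float),
        expectation=np.asarray(out_e, dtype=float),
        final_state=state,
        log_base=log_base,
        score_after_update=score_after_update,
    )
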