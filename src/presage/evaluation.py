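"""Static hindsight benchmark and dynamic-vs-static comparison.

The *static empirical surprisal* of a record is the hindsight benchmark:
fit the same distributional family to the participant's complete record,
then score every day's observation under that single fitted distribution.
Comparing dynamic (prospectively updated) surprisal to this benchmark
isolates what is lost or gained by having to learn a person's distribution
on the fly:

* exercise -> Bernoulli with ``p_hat = k / T``, clipped to
  ``[1/(2T), 1 - 1/(2T)]`` so all-or-nothing records keep finite surprisal;
* sleep -> Normal MLE (mean, variance with a small floor) discretized over
  integer hours exactly as the dynamic model;
* stress -> hurdle-Gamma MLE (clipped zero rate + Gamma MLE on the nonzero
  values), binned exactly as the dynamic model.

Group summaries are frequentist across participants: per-day means with
95% confidence intervals from the standard error of the mean, deliberately
ignoring each individual surprisal value's own uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

from .conjugate import discretize_normal, round_half_up
from .priors import gamma_mle
from .stress import HurdleGammaPosterior, stress_predictive
from .surprisal import safe_surprisal

__all__ = [
    "StaticReference",
    "static_reference",
    "compare",
    "summarize_expectations",
]

Z_95 = 1.96


@dataclass
class StaticReference:
    """Full-record fitted distribution and per-day static surprisal."""

    variable: str
    params: dict
    day: np.ndarray
    surprisal: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.day, "static_surprisal": self.surprisal})


def _clip_rate(p: float, t: int) -> float:
    lo = 1.0 / (2.0 * t)
    return float(min(max(p, lo), 1.0 - lo))


def static_reference(
    values: Sequence[float],
    variable: str,
    *,
    days: Optional[Sequence[int]] = None,
    log_base: Any = "e",
    sleep_var_floor: float = 0.25,
    bin_width: float = 1.0,
    support_max: float = 100.0,
) -> StaticReference:
    """Fit the hindsight distribution to a complete record and score it.

    ``values`` is the participant's full record for one variable (missing
    entries as NaN are dropped); ``days`` optionally carries the original
    day indices so output aligns with the dynamic trajectory.
    """
    x = np.asarray(list(values), dtype=float)
    if days is None:
        day_idx = np.arange(1, len(x) + 1)
    else:
        day_idx = np.asarray(list(days), dtype=int)
        if len(day_idx) != len(x):
            raise ValueError("days and values must have equal length")
    keep = ~np.isnan(x)
    x, day_idx = x[keep], day_idx[keep]
    t = len(x)
    if t == 0:
        raise ValueError("record is empty")

    if variable == "exercise":
        if not set(np.unique(x)) <= {0.0, 1.0}:
            raise ValueError("exercise record must be binary")
        k = int(x.sum())
        p_hat = _clip_rate(k / t, t)
        surp = np.where(x == 1, -np.log(p_hat), -np.log(1.0 - p_hat))
        params = {"p_hat": p_hat, "k": k, "t": t}
    elif variable == "sleep":
        if np.any(x < 0):
            raise ValueError("sleep record must be non-negative")
        mean = float(x.mean())
        var = float(x.var())  # MLE (ddof=0)
        var = max(var, sleep_var_floor)
        pred = discretize_normal(mean, math.sqrt(var))
        surp = np.array(
            [safe_surprisal(pred.mass_at(round_half_up(v)), log_base) for v in x]
        )
        params = {"mean": mean, "var": var}
    elif variable == "stress":
        if np.any(x < 0):
            raise ValueError("stress record must be non-negative")
        nonzero = x[x > 0]
        if nonzero.size < 2:
            raise ValueError("stress record needs at least two nonzero values")
        zero_rate = _clip_rate(float(np.mean(x == 0)), t)
        shape, rate = gamma_mle(nonzero)
        point = HurdleGammaPosterior(
            p_zero=np.array([zero_rate]),
            shape=np.array([shape]),
            rate=np.array([rate]),
        )
        pred = stress_predictive(point, bin_width=bin_width, support_max=support_max)
        surp = np.array([safe_surprisal(pred.mass_at(v), log_base) for v in x])
        params = {"zero_rate": zero_rate, "shape": shape, "rate": rate}
    else:
        raise ValueError(f"unknown variable {variable!r}")

    if variable == "exercise":
        surp = surp / (1.0 if log_base in ("e", math.e, None) else math.log(2.0))
    return StaticReference(variable=variable, params=params, day=day_idx, surprisal=surp)


def _daily_summary(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Per-day mean, SE, normal 95% CI and n over participants."""
    grouped = df.groupby("day")[value_col]
    out = grouped.agg(estimate="mean", sd=lambda s: s.std(ddof=1), n="count")
    out = out.reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out["ci_lo"] = out["estimate"] - Z_95 * out["se"]
    out["ci_hi"] = out["estimate"] + Z_95 * out["se"]
    # n = 1 leaves the SE undefined; flag rather than drop the day
    out["flagged"] = out["n"] < 2
    return out[["day", "estimate", "se", "ci_lo", "ci_hi", "n", "flagged"]]


def compare(dynamic: pd.DataFrame, static: pd.DataFrame) -> pd.DataFrame:
    """Per-day group mean of (dynamic - static) surprisal with 95% CI.

    Both inputs are tidy frames with columns ``participant_id, day,
    surprisal``; only participant-days present in both contribute.
    """
    for name, df in (("dynamic", dynamic), ("static", static)):
        missing = {"participant_id", "day", "surprisal"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} frame missing columns {sorted(missing)}")
    merged = dynamic.merge(
        static,
        on=["participant_id", "day"],
        suffixes=("_dynamic", "_static"),
        how="inner",
    )
    if merged.empty:
        raise ValueError("no matching participant-days between dynamic and static")
    merged["difference"] = merged["surprisal_dynamic"] - merged["surprisal_static"]
    return _daily_summary(merged, "difference")


def summarize_expectations(expectations: pd.DataFrame, value_col: str = "expectation") -> pd.DataFrame:
    """Per-day group mean and 95% CI of expected values across participants."""
    if expectations.empty:
        raise ValueError("no expectations to summarize")
    missing = {"day", value_col} - set(expectations.columns)
    if missing:
        raise ValueError(f"expectations frame missing columns {sorted(missing)}")
    return _daily_summary(expectations, value_col)
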