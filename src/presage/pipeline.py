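"""End-to-end orchestration: data -> priors -> trajectories -> summaries.

:func:`run_pipeline` ties the pieces together for each requested variable and
prior condition: build the prior (leave-one-out across the cohort for the
empirical condition), run the sequential model over every participant's
record, fit the static hindsight reference, and reduce to tidy per-day group
tables.  All randomness derives deterministically from ``base_seed``, so a
rerun with the same config is bit-identical.

Outputs (written under ``out_dir`` when given):

* ``trajectories.csv`` — per participant/variable/condition/day dynamic
  predictive mass, surprisal and forecast expectation;
* ``static.csv`` — per participant/variable/day static surprisal;
* ``expectations_by_day.csv``, ``surprisal_by_day.csv``,
  ``difference_by_day.csv`` — per-day group summaries with 95% CIs;
* ``manifest.json`` — config, seed and config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import CohortConfig, simulate_cohort
from .conjugate import BetaBernoulliState, NormalMeanState
from .evaluation import compare, static_reference, summarize_expectations, _daily_summary
from .io import read_diary, write_diary
from .priors import (
    PriorSpec,
    empirical_prior_exercise,
    empirical_prior_sleep,
    empirical_prior_stress,
    uninformative_prior,
)
from .stress import HurdleGammaModel
from .surprisal import run_prequential

__all__ = ["RunConfig", "run_pipeline", "load_config"]

_VALUE_COLUMN = {"exercise": "exercise", "sleep": "sleep_hours", "stress": "stress"}


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Exactly one of ``input_path`` (a diary CSV) or ``simulate`` (a cohort
    config) must be given.  ``score_after_update=True`` is the convention
    under which the dynamic-vs-static benchmark is computed (see
    docs/methods.md); set it to False for strict one-step-ahead scoring.
    """

    input_path: Optional[str] = None
    simulate: Optional[CohortConfig] = None
    variables: Sequence[str] = ("exercise", "sleep", "stress")
    prior_conditions: Sequence[str] = ("uninformative", "empirical")
    log_base: Any = "e"
    score_after_update: bool = True
    sleep_obs_var: float = 2.25
    sleep_var_floor: float = 0.25
    stress_cv: float = 0.5
    n_draws: int = 2000
    n_warmup: int = 1000
    bin_width: float = 1.0
    support_max: float = 100.0
    base_seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("exactly one of input_path or simulate must be set")
        unknown = set(self.variables) - set(_VALUE_COLUMN)
        if unknown:
            raise ValueError(f"unknown variables: {sorted(unknown)}")
        unknown = set(self.prior_conditions) - {"uninformative", "empirical"}
        if unknown:
            raise ValueError(f"unknown prior conditions: {sorted(unknown)}")


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "simulate" in raw and raw["simulate"] is not None:
        raw["simulate"] = CohortConfig(**raw["simulate"])
    return RunConfig(**raw)


def _person_records(data: pd.DataFrame, column: str) -> dict[str, pd.DataFrame]:
    out = {}
    for pid, grp in data.groupby("participant_id", sort=True):
        out[pid] = grp.sort_values("day")[["day", column]]
    return out


def _prior_for(
    data: pd.DataFrame,
    variable: str,
    condition: str,
    pid: str,
    config: RunConfig,
) -> PriorSpec:
    if condition == "uninformative":
        return uninformative_prior(variable, sleep_obs_var=config.sleep_obs_var)
    others = data[data["participant_id"] != pid]
    if variable == "exercise":
        rates = others.groupby("participant_id")["exercise"].mean().dropna()
        return empirical_prior_exercise(rates.to_numpy())
    if variable == "sleep":
        records = [
            grp["sleep_hours"].dropna().to_numpy()
            for _, grp in others.groupby("participant_id")
        ]
        return empirical_prior_sleep(records, var_floor=config.sleep_var_floor)
    stress = others["stress"].dropna()
    zero_rates = (
        others.assign(is_zero=lambda d: (d["stress"] == 0).where(d["stress"].notna()))
        .groupby("participant_id")["is_zero"]
        .mean()
        .dropna()
    )
    return empirical_prior_stress(
        stress[stress > 0].to_numpy(), zero_rates.to_numpy(), cv=config.stress_cv
    )


def _initial_model(
    prior: PriorSpec, config: RunConfig, participant_index: int, condition_index: int
):
    if prior.variable in ("exercise", "sleep"):
        return prior.parameters
    return HurdleGammaModel(
        prior.parameters,
        n_draws=config.n_draws,
        n_warmup=config.n_warmup,
        base_seed=config.base_seed,
        key=(participant_index, condition_index),
        bin_width=config.bin_width,
        support_max=config.support_max,
    )


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every requested variable x prior condition over the cohort."""
    if config.simulate is not None:
        data = simulate_cohort(config.simulate)
    else:
        data = read_diary(config.input_path)
    if data.empty:
        raise ValueError("diary dataset is empty")

    participants = sorted(data["participant_id"].unique())
    traj_rows, static_rows = [], []

    for variable in config.variables:
        column = _VALUE_COLUMN[variable]
        records = _person_records(data, column)
        # static reference is prior-free: one fit per participant
        for pid in participants:
            rec = records[pid]
            ref = static_reference(
                rec[column].to_numpy(),
                variable,
                days=rec["day"].to_numpy(),
                log_base=config.log_base,
                sleep_var_floor=config.sleep_var_floor,
                bin_width=config.bin_width,
                support_max=config.support_max,
            )
            static_rows.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "variable": variable,
                        "day": ref.day,
                        "surprisal": ref.surprisal,
                    }
                )
            )
        for c_idx, condition in enumerate(config.prior_conditions):
            for p_idx, pid in enumerate(participants):
                rec = records[pid]
                prior = _prior_for(data, variable, condition, pid, config)
                model = _initial_model(prior, config, p_idx, c_idx)
                traj = run_prequential(
                    rec[column].to_numpy(),
                    model,
                    days=rec["day"].to_numpy(),
                    score_after_update=config.score_after_update,
                    log_base=config.log_base,
                )
                frame = traj.to_frame()
                frame.insert(0, "participant_id", pid)
                frame.insert(1, "variable", variable)
                frame.insert(2, "prior_condition", condition)
                traj_rows.append(frame)

    trajectories = pd.concat(traj_rows, ignore_index=True)
    static = pd.concat(static_rows, ignore_index=True)

    expectation_parts, surprisal_parts, difference_parts = [], [], []
    for (variable, condition), grp in trajectories.groupby(
        ["variable", "prior_condition"], sort=True
    ):
        exp_summary = summarize_expectations(grp[["day", "expectation"]])
        surp_summary = _daily_summary(grp[["day", "surprisal"]], "surprisal")
        stat = static[static["variable"] == variable]
        diff = compare(
            grp[["participant_id", "day", "surprisal"]],
            stat[["participant_id", "day", "surprisal"]],
        )
        for part, sink in (
            (exp_summary, expectation_parts),
            (surp_summary, surprisal_parts),
            (diff, difference_parts),
        ):
            part = part.copy()
            part.insert(0, "variable", variable)
            part.insert(1, "prior_condition", condition)
            sink.append(part)

    results = {
        "trajectories": trajectories,
        "static": static,
        "expectations_by_day": pd.concat(expectation_parts, ignore_index=True),
        "surprisal_by_day": pd.concat(surprisal_parts, ignore_index=True),
        "difference_by_day": pd.concat(difference_parts, ignore_index=True),
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in results.items():
            df.to_csv(out / f"{name}.csv", index=False)
        manifest = _manifest(config)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results


def _manifest(config: RunConfig) -> dict:
    cfg = asdict(config)
    payload = json.dumps(cfg, sort_keys=True, default=str)
    return {
        "config": cfg,
        "base_seed": config.base_seed,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
    }
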