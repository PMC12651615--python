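"""Diary CSV reading, writing and validation.

The interchange format is a plain long/wide CSV with one row per
participant-day and the columns ``participant_id, day, stress, sleep_hours,
exercise``; empty cells mark missing observations.  Validation is strict and
reports offending rows by position so malformed exports fail loudly before
any modeling happens.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = ["DIARY_COLUMNS", "read_diary", "write_diary", "validate_diary"]

DIARY_COLUMNS = ["participant_id", "day", "stress", "sleep_hours", "exercise"]


class DiarySchemaError(ValueError):
    """Raised when a diary table violates the expected schema."""


def validate_diary(df: pd.DataFrame) -> pd.DataFrame:
    """Validate (and lightly coerce) a diary table, returning a clean copy."""
    missing = [c for c in DIARY_COLUMNS if c not in df.columns]
    if missing:
        raise DiarySchemaError(f"diary is missing required columns: {missing}")
    out = df.loc[:, DIARY_COLUMNS].copy()
    out["participant_id"] = out["participant_id"].astype(str)

    day = pd.to_numeric(out["day"], errors="coerce")
    bad = out.index[day.isna() | (day < 1) | (day != day.round())]
    if len(bad):
        raise DiarySchemaError(f"non-positive or non-integer day at rows {list(bad[:10])}")
    out["day"] = day.astype(int)

    dups = out.duplicated(subset=["participant_id", "day"])
    if dups.any():
        raise DiarySchemaError(
            f"duplicate (participant_id, day) at rows {list(out.index[dups][:10])}"
        )

    for col in ("stress", "sleep_hours", "exercise"):
        out[col] = pd.to_numeric(out[col], errors="coerce")

    ex = out["exercise"]
    bad = out.index[ex.notna() & ~ex.isin([0.0, 1.0])]
    if len(bad):
        raise DiarySchemaError(f"exercise must be 0, 1 or empty; bad rows {list(bad[:10])}")
    for col in ("stress", "sleep_hours"):
        vals = out[col]
        bad = out.index[vals.notna() & (vals < 0)]
        if len(bad):
            raise DiarySchemaError(f"{col} must be non-negative; bad rows {list(bad[:10])}")
    return out


def read_diary(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a diary CSV."""
    df = pd.read_csv(path)
    return validate_diary(df)


def write_diary(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Validate and write a diary table as CSV (empty cells for missing)."""
    validate_diary(df).to_csv(path, index=False)
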