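"""Tidy trial-table I/O with validation.

One row per trial, comma-delimited, header fixed to
``participant_id, order_group, session_index, condition, trial_index,
trial_type, denotation, count, correct_response, response, rt_ms,
is_error, is_miss``.  Missing response / RT are empty fields (a miss).
Reading validates the record invariants and fails naming the violated rule
and the offending data row.  ``NaCl`` is accepted as an input alias for the
placebo condition.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .generator import ALCOHOL, CONGRUENT, INCONGRUENT, PLACEBO, TRIAL_COLUMNS

__all__ = ["TrialTableError", "read_trials", "write_trials", "TRIAL_COLUMNS"]

_FLAG_COLUMNS = ("is_error", "is_miss")


class TrialTableError(ValueError):
    """A trial file violates the format or a record invariant."""


def write_trials(
    trials: pd.DataFrame,
    path: str | Path,
    extra_columns: tuple[str, ...] = (),
) -> None:
    """Write the canonical trial CSV (plus optional extra flag columns)."""
    cols = TRIAL_COLUMNS + [c for c in extra_columns if c in trials.columns]
    out = trials[cols].copy()
    for col in _FLAG_COLUMNS + tuple(extra_columns):
        if col in out.columns:
            out[col] = out[col].astype(int)
    out["response"] = out["response"].astype("Int64")
    out.to_csv(path, index=False)


def _fail(rule: str, rows: pd.Index) -> None:
    # +2: 1-based data rows below the header line
    where = [int(r) + 2 for r in rows[:5]]
    raise TrialTableError(f"{rule} (file row(s) {where})")


def read_trials(
    path: str | Path,
    extra_columns: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Read and validate a trial CSV written by :func:`write_trials`."""
    df = pd.read_csv(
        path,
        dtype={
            "participant_id": str,
            "order_group": str,
            "condition": str,
            "trial_type": str,
        },
    )
    expected = TRIAL_COLUMNS + list(extra_columns)
    if list(df.columns) != expected:
        raise TrialTableError(
            f"malformed header: expected {expected}, found {list(df.columns)}"
        )
    df["condition"] = df["condition"].replace({"NaCl": PLACEBO})

    for col in _FLAG_COLUMNS + tuple(extra_columns):
        bad = ~df[col].isin([0, 1])
        if bad.any():
            _fail(f"{col} must be 0 or 1", df.index[bad])
        df[col] = df[col].astype(bool)
    df["response"] = df["response"].astype(float)

    has_resp = df["response"].notna()
    has_rt = df["rt_ms"].notna()
    if (bad := has_resp & ~has_rt).any():
        _fail("response present but rt_ms absent", df.index[bad])
    if (bad := ~has_resp & has_rt).any():
        _fail("rt_ms present but response absent", df.index[bad])
    if (bad := df["is_miss"] & (has_resp | has_rt | ~df["is_error"])).any():
        _fail("a miss must have no response/RT and count as an error", df.index[bad])
    if (bad := ~df["condition"].isin([ALCOHOL, PLACEBO])).any():
        _fail(f"condition must be '{ALCOHOL}' or '{PLACEBO}'", df.index[bad])
    if (bad := ~df["trial_type"].isin([INCONGRUENT, CONGRUENT])).any():
        _fail("unknown trial_type", df.index[bad])
    congruent = df["trial_type"] == CONGRUENT
    if (bad := congruent != (df["denotation"] == df["count"])).any():
        _fail("trial_type must be congruent iff denotation equals count", df.index[bad])
    if (bad := df["correct_response"] != df["count"]).any():
        _fail("correct_response must equal count", df.index[bad])
    if (bad := ~df["denotation"].isin([1, 2, 3, 4]) | ~df["count"].isin([1, 2, 3, 4])).any():
        _fail("denotation and count must be digits 1-4", df.index[bad])

    increasing = (
        df.groupby(["participant_id", "session_index"], sort=False)["trial_index"]
        .diff()
        .fillna(1)
    )
    if (bad := increasing <= 0).any():
        _fail(
            "trial_index must be strictly increasing within participant x session",
            df.index[bad],
        )
    rt_bad = has_rt & (df["rt_ms"] <= 0)
    if rt_bad.any():
        _fail("rt_ms must be positive when present", df.index[rt_bad])
    return df
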