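"""Outcome measures: cell summaries, interference scores, reliability.

Per participant x condition x trial type the pipeline computes the mean
correct-trial RT (after outlier removal), the error rate over *all* trials
of the cell (misses included), and the inverse efficiency score
IES = RT / (1 - ER), which folds the speed-accuracy trade-off into a single
time cost.  Interference scores are exact incongruent - congruent
differences per measure.  Internal consistency is estimated from an
odd/even split of trials with the Spearman-Brown correction
alpha = 2r / (1 + r).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CleaningConfig
from .generator import CONGRUENT, INCONGRUENT
from .preprocessing import winsorize_scores

__all__ = [
    "MEASURES",
    "ReliabilityResult",
    "compute_cell_summaries",
    "compute_interference",
    "winsorize_score_table",
    "split_half_reliability",
]

logger = logging.getLogger(__name__)

MEASURES = ("rt", "er", "ies")
_CELL = ["participant_id", "condition", "trial_type"]


def compute_cell_summaries(clean_trials: pd.DataFrame) -> pd.DataFrame:
    """Aggregate cleaned trials into per-cell summaries.

    ``mean_rt_ms`` averages retained correct trials (errors and flagged RT
    outliers removed); ``er`` divides errors (incl. misses) by *all* trials
    of the cell, so RT-outlier removal never shrinks its denominator.
    Cells with ER = 1 get an undefined (NaN) IES and ``valid = False``.
    """
    t = clean_trials
    retained = ~t["is_error"]
    if "rt_outlier" in t.columns:
        retained &= ~t["rt_outlier"]
    rt_part = (
        t.loc[retained]
        .groupby(_CELL, sort=True)
        .agg(mean_rt_ms=("rt_ms", "mean"), n_rt_trials=("rt_ms", "size"))
    )
    er_part = (
        t.groupby(_CELL, sort=True)
        .agg(n_trials=("is_error", "size"), n_errors=("is_error", "sum"))
    )
    cells = er_part.join(rt_part).reset_index()
    cells["n_rt_trials"] = cells["n_rt_trials"].fillna(0).astype(int)
    cells["er"] = cells["n_errors"] / cells["n_trials"]
    cells["valid"] = cells["er"] < 1.0
    with np.errstate(divide="ignore"):
        cells["ies_ms"] = np.where(
            cells["valid"], cells["mean_rt_ms"] / (1.0 - cells["er"]), np.nan
        )
    return cells[
        _CELL + ["mean_rt_ms", "er", "ies_ms", "n_rt_trials", "n_trials", "valid"]
    ]


def compute_interference(cells: pd.DataFrame) -> pd.DataFrame:
    """Build the wide participant x condition score table.

    Columns: ``{measure}_incongruent``, ``{measure}_congruent`` and
    ``{measure}_interference`` (exact difference) for measure in rt/er/ies.
    Participants missing a cell are dropped with a log entry.
    """
    value_cols = {"rt": "mean_rt_ms", "er": "er", "ies": "ies_ms"}
    wide = cells.pivot_table(
        index=["participant_id", "condition"],
        columns="trial_type",
        values=list(value_cols.values()),
        aggfunc="first",
    )
    complete = wide.notna().all(axis=1).groupby("participant_id").all()
    dropped = complete.index[~complete].tolist()
    if dropped:
        logger.info("participants dropped for missing cells: %s", dropped)
        wide = wide[~wide.index.get_level_values("participant_id").isin(dropped)]

    out = pd.DataFrame(index=wide.index)
    for measure, col in value_cols.items():
        inc = wide[(col, INCONGRUENT)]
        con = wide[(col, CONGRUENT)]
        out[f"{measure}_incongruent"] = inc
        out[f"{measure}_congruent"] = con
        out[f"{measure}_interference"] = inc - con
    return out.reset_index()


def winsorize_score_table(
    score_table: pd.DataFrame,
    config: CleaningConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Winsorize participant-level scores within their comparison groups.

    Cell scores are winsorized per measure x condition x trial type across
    participants; interference scores are then recomputed from the
    winsorized cells and (optionally) winsorized once more per measure x
    condition.  Returns the adjusted table and a log of replacements.
    """
    config = config or CleaningConfig()
    out = score_table.copy()
    logs: list[pd.DataFrame] = []

    def _apply(col: str, mask: pd.Series) -> None:
        vals, log = winsorize_scores(out.loc[mask, col].to_numpy(), config)
        out.loc[mask, col] = vals
        if len(log):
            log = log.assign(column=col)
            logs.append(log)

    for condition in sorted(out["condition"].unique()):
        mask = out["condition"] == condition
        for measure in MEASURES:
            for cell in ("incongruent", "congruent"):
                _apply(f"{measure}_{cell}", mask)
    for measure in MEASURES:
        out[f"{measure}_interference"] = (
            out[f"{measure}_incongruent"] - out[f"{measure}_congruent"]
        )
    if config.winsorize_interference:
        for condition in sorted(out["condition"].unique()):
            mask = out["condition"] == condition
            for measure in MEASURES:
                _apply(f"{measure}_interference", mask)

    log = (
        pd.concat(logs, ignore_index=True)
        if logs
        else pd.DataFrame(columns=["index", "original", "replaced", "column"])
    )
    return out, log


@dataclass
class ReliabilityResult:
    """Split-half reliability for one measure in one condition."""

    measure: str
    condition: str
    split_half_r: float
    cronbach_alpha: float
    n_participants: int


def spearman_brown(r: float) -> float:
    """Spearman-Brown prophecy correction for a double-length test."""
    return 2.0 * r / (1.0 + r)


def _half_scores(trials: pd.DataFrame, measure: str) -> pd.Series:
    """Per participant x condition x half: measure aggregated over trial types."""
    t = trials
    retained = ~t["is_error"]
    if "rt_outlier" in t.columns:
        retained &= ~t["rt_outlier"]
    keys = ["participant_id", "condition", "half", "trial_type"]
    rt = t.loc[retained].groupby(keys)["rt_ms"].mean()
    er = t.groupby(keys)["is_error"].mean()
    if measure == "rt":
        cell = rt
    elif measure == "er":
        cell = er
    elif measure == "ies":
        cell = rt / (1.0 - er)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    # average the two trial-type cells (balanced by design)
    return cell.groupby(["participant_id", "condition", "half"]).mean()


def split_half_reliability(
    clean_trials: pd.DataFrame, measure: str
) -> list[ReliabilityResult]:
    """Odd/even split-half reliability with Spearman-Brown adjustment.

    Trials are split by parity of ``trial_index`` within participant x
    condition x trial type (preserving time-on-task balance); the measure
    is computed per half (aggregated over trial types), correlated across
    participants, and adjusted with alpha = 2r / (1 + r).  Unwinsorized
    scores are used: winsorization is defined on full-sample scores only.
    """
    t = clean_trials.copy()
    if t["participant_id"].nunique() < 4:
        raise ValueError("split-half reliability needs at least 4 participants")
    t["half"] = np.where(t["trial_index"] % 2 == 1, "odd", "even")
    halves = _half_scores(t, measure).unstack("half")
    results = []
    for condition, grp in halves.groupby("condition"):
        grp = grp.dropna()
        odd = grp["odd"].to_numpy()
        even = grp["even"].to_numpy()
        if np.std(odd) == 0 or np.std(even) == 0:
            raise ValueError(
                f"split-half correlation undefined for {measure}/{condition}: "
                "zero variance in a half"
            )
        r = float(np.corrcoef(odd, even)[0, 1])
        results.append(
            ReliabilityResult(
                measure=measure,
                condition=str(condition),
                split_half_r=r,
                cronbach_alpha=spearman_brown(r),
                n_participants=len(grp),
            )
        )
    return results


def reliability_table(clean_trials: pd.DataFrame) -> pd.DataFrame:
    """Reliability for all three measures, one row per measure x condition."""
    rows = []
    for measure in MEASURES:
        for res in split_half_reliability(clean_trials, measure):
            rows.append(
                {
                    "measure": measure,
                    "condition": res.condition,
                    "split_half_r": res.split_half_r,
                    "cronbach_alpha": res.cronbach_alpha,
                    "n_participants": res.n_participants,
                }
            )
    return pd.DataFrame(rows)
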