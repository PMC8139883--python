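"""Masking-check analyses: delta plots, conflict adaptation, button effects.

These three analyses probe whether an alcohol x trial-type interaction is
hiding in a specific property of the task even when the overall 2 x 2
interaction is null:

* **Delta plot** — interference as a function of RT quantile.  Per
  participant x condition x trial type, retained correct RTs are
  Vincentized: sorted and cut into four contiguous equal-count bins
  (remainder trials assigned to the earliest bins); per-quantile
  interference is the incongruent - congruent bin-mean difference, tested
  with a 2 x 4 (alcohol x quantile) within ANOVA.
* **Conflict adaptation (Gratton)** — RT cell means by condition x previous
  x current trial type, first trial of each session excluded; the previous
  type is taken from presentation order regardless of that trial's accuracy
  (its type is known even when its RT is excluded).  Tested with a
  2 x 2 x 2 within ANOVA; the adaptation score is interference after
  congruent minus interference after incongruent trials.
* **Button analysis** — interference computed within trials sharing the
  same required response button (1-4 digits), tested with a 2 x 4
  (alcohol x button) within ANOVA on the interference score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .generator import CONGRUENT, INCONGRUENT
from .inference import AnovaResult, rm_anova_within

__all__ = [
    "DeltaPlotResult",
    "GrattonResult",
    "delta_plot",
    "gratton_analysis",
    "button_analysis",
]

logger = logging.getLogger(__name__)

N_QUANTILES = 4
MIN_TRIALS_PER_QUANTILE_CELL = 8


def _retained(trials: pd.DataFrame) -> pd.DataFrame:
    keep = ~trials["is_error"]
    if "rt_outlier" in trials.columns:
        keep &= ~trials["rt_outlier"]
    return trials.loc[keep]


@dataclass
class DeltaPlotResult:
    """Vincentized interference by RT quantile plus its 2 x 4 ANOVA."""

    scores: pd.DataFrame  # participant x condition x quantile interference
    cell_means: pd.DataFrame  # condition x quantile mean interference
    anova: AnovaResult
    dropped_participants: list[str]


def _quantile_means(rts: np.ndarray, n_bins: int) -> np.ndarray:
    """Means of contiguous equal-count bins of the sorted RTs.

    ``np.array_split`` gives the remainder to the earliest bins.
    """
    return np.array([b.mean() for b in np.array_split(np.sort(rts), n_bins)])


def delta_plot(clean_trials: pd.DataFrame, n_quantiles: int = N_QUANTILES) -> DeltaPlotResult:
    """Delta-plot analysis of RT interference across quantiles."""
    kept = _retained(clean_trials)
    grouped = kept.groupby(["participant_id", "condition", "trial_type"])
    bin_means: dict[tuple, np.ndarray] = {}
    too_few: set[str] = set()
    for key, grp in grouped:
        if len(grp) < MIN_TRIALS_PER_QUANTILE_CELL:
            too_few.add(key[0])
        else:
            bin_means[key] = _quantile_means(grp["rt_ms"].to_numpy(), n_quantiles)
    for pid in sorted(too_few):
        logger.info("delta plot: participant %s dropped (<%d trials in a cell)",
                    pid, MIN_TRIALS_PER_QUANTILE_CELL)
    rows = []
    for (pid, cond, ttype), means in bin_means.items():
        if pid in too_few:
            continue
        for q, m in enumerate(means, start=1):
            rows.append(
                {
                    "participant_id": pid,
                    "condition": cond,
                    "trial_type": ttype,
                    "quantile": q,
                    "mean_rt_ms": m,
                }
            )
    long = pd.DataFrame(rows)
    wide = long.pivot_table(
        index=["participant_id", "condition", "quantile"],
        columns="trial_type",
        values="mean_rt_ms",
    )
    scores = (
        (wide[INCONGRUENT] - wide[CONGRUENT])
        .rename("interference_ms")
        .reset_index()
    )
    anova = rm_anova_within(
        scores, dv="interference_ms", within=["condition", "quantile"]
    )
    cell_means = (
        scores.groupby(["condition", "quantile"])["interference_ms"]
        .mean()
        .reset_index()
    )
    return DeltaPlotResult(
        scores=scores,
        cell_means=cell_means,
        anova=anova,
        dropped_participants=sorted(too_few),
    )


def plot_delta(result: DeltaPlotResult, path: str) -> None:
    """Render the delta plot (mean interference by quantile per condition).

    Requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, grp in result.cell_means.groupby("condition"):
        ax.plot(grp["quantile"], grp["interference_ms"], marker="o", label=cond)
    ax.set_xlabel("RT quantile")
    ax.set_ylabel("interference (ms)")
    ax.set_xticks(sorted(result.cell_means["quantile"].unique()))
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class GrattonResult:
    """Sequential (previous x current trial type) RT analysis."""

    cell_means: pd.DataFrame  # participant x condition x prev x current mean RT
    adaptation: pd.DataFrame  # participant x condition conflict_adaptation_ms
    mean_adaptation_ms: float
    anova: AnovaResult
    dropped_participants: list[str]


def _with_previous_type(trials: pd.DataFrame) -> pd.DataFrame:
    """Attach the previous trial's type; drop each session's first trial."""
    t = trials.sort_values(
        ["participant_id", "session_index", "trial_index"], kind="stable"
    ).copy()
    grp = t.groupby(["participant_id", "session_index"], sort=False)
    t["previous_type"] = grp["trial_type"].shift(1)
    return t[t["previous_type"].notna()]


def gratton_analysis(clean_trials: pd.DataFrame) -> GrattonResult:
    """Conflict-adaptation analysis (2 x 2 x 2 within ANOVA on RT)."""
    seq = _with_previous_type(clean_trials)
    kept = _retained(seq)
    cells = (
        kept.groupby(["participant_id", "condition", "previous_type", "trial_type"])
        ["rt_ms"].mean().rename("mean_rt_ms").reset_index()
    )
    counts = cells.groupby("participant_id").size()
    complete = counts.index[counts == 8]
    dropped = sorted(set(counts.index) - set(complete))
    if dropped:
        logger.info("gratton: participants dropped for empty sequential cells: %s",
                    dropped)
    cells = cells[cells["participant_id"].isin(complete)]

    wide = cells.pivot_table(
        index=["participant_id", "condition"],
        columns=["previous_type", "trial_type"],
        values="mean_rt_ms",
    )
    interference_after_con = (
        wide[(CONGRUENT, INCONGRUENT)] - wide[(CONGRUENT, CONGRUENT)]
    )
    interference_after_inc = (
        wide[(INCONGRUENT, INCONGRUENT)] - wide[(INCONGRUENT, CONGRUENT)]
    )
    adaptation = (
        (interference_after_con - interference_after_inc)
        .rename("conflict_adaptation_ms")
        .reset_index()
    )
    anova = rm_anova_within(
        cells,
        dv="mean_rt_ms",
        within=["condition", "previous_type", "trial_type"],
    )
    return GrattonResult(
        cell_means=cells,
        adaptation=adaptation,
        mean_adaptation_ms=float(adaptation["conflict_adaptation_ms"].mean()),
        anova=anova,
        dropped_participants=dropped,
    )


def button_analysis(clean_trials: pd.DataFrame) -> tuple[pd.DataFrame, AnovaResult]:
    """Interference per response button with its 2 x 4 within ANOVA.

    Interference is computed among trials requiring the same button
    (i.e. the same digit count); participants with an empty button x
    trial-type cell are dropped.
    """
    kept = _retained(clean_trials)
    cells = (
        kept.groupby(["participant_id", "condition", "correct_response", "trial_type"])
        ["rt_ms"].mean().rename("mean_rt_ms").reset_index()
        .rename(columns={"correct_response": "button"})
    )
    wide = cells.pivot_table(
        index=["participant_id", "condition", "button"],
        columns="trial_type",
        values="mean_rt_ms",
    )
    scores = (
        (wide[INCONGRUENT] - wide[CONGRUENT]).rename("interference_ms").reset_index()
    )
    counts = scores.dropna().groupby("participant_id").size()
    n_cells = scores["condition"].nunique() * scores["button"].nunique()
    complete = counts.index[counts == n_cells]
    dropped = sorted(
        set(scores["participant_id"].unique()) - set(complete)
    )
    if dropped:
        logger.info("button analysis: participants dropped: %s", dropped)
    scores = scores[scores["participant_id"].isin(complete)].dropna()
    anova = rm_anova_within(
        scores, dv="interference_ms", within=["condition", "button"]
    )
    return scores, anova
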