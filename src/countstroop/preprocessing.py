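"""Trial- and participant-level cleaning for the Counting Stroop analysis.

The fixed order of operations is:

1. :func:`mark_errors_and_misses` — absent responses become misses and count
   as errors.
2. :func:`exclude_rt_outliers` — within participant x session x trial type,
   correct-trial RTs farther than ``mad_multiplier`` (default 3.32) *raw*
   median absolute deviations from the group median are flagged.  Flagged
   trials leave every RT-based aggregate but still count in error-rate
   denominators.
3. Participant exclusion via :func:`exclude_below_chance` — a participant is
   removed (from both sessions) when, in any session x trial type, the exact
   binomial probability of exceeding the observed number of correct
   responses by chance (hit probability 0.25) is above 0.01.
4. :func:`winsorize_scores` — participant-level scores beyond mean +- 3 SD
   of their group vector are replaced by the boundary, computed in a single
   pass from the original vector with the sample (n-1) SD.

The MAD is used unscaled (no 1.4826 consistency constant): the 3.32
multiplier already incorporates it.  A degenerate group (MAD = 0) excludes
nothing, since ties at the median make the criterion uninformative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import CleaningConfig

__all__ = [
    "MalformedRecordError",
    "CleaningReport",
    "mark_errors_and_misses",
    "exclude_rt_outliers",
    "exclude_below_chance",
    "winsorize_scores",
    "min_surviving_accuracy",
    "clean_trials",
]

logger = logging.getLogger(__name__)

MIN_TRIALS_FOR_MAD = 3


class MalformedRecordError(ValueError):
    """A trial record violates the table invariants."""


@dataclass
class CleaningReport:
    """Everything the cleaning stage decided, reconciled with raw counts."""

    #: per participant x session x trial_type: n_trials, n_misses, n_errors,
    #: n_rt_outliers, n_rt_retained
    trial_counts: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: per participant x session x trial_type: n_correct and the exact
    #: binomial survivor probability, plus the exclusion flag
    below_chance: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: participants removed by the below-chance rule
    excluded_participants: list[str] = field(default_factory=list)
    #: winsorization log: one row per replaced score
    winsor_log: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_text(self) -> str:
        lines = ["Cleaning report", "=" * 15, ""]
        tc = self.trial_counts
        if len(tc):
            lines.append(
                f"trials: {int(tc['n_trials'].sum())}  "
                f"misses: {int(tc['n_misses'].sum())}  "
                f"errors (incl. misses): {int(tc['n_errors'].sum())}  "
                f"RT outliers removed: {int(tc['n_rt_outliers'].sum())}"
            )
        if self.excluded_participants:
            lines.append(
                "below-chance exclusions: " + ", ".join(self.excluded_participants)
            )
        else:
            lines.append("below-chance exclusions: none")
        lines.append(f"winsorized scores: {len(self.winsor_log)}")
        return "\n".join(lines) + "\n"


def mark_errors_and_misses(trials: pd.DataFrame) -> pd.DataFrame:
    """Finalize the ``is_error`` / ``is_miss`` flags from the raw responses.

    Misses (absent response) are errors.  A present response with an absent
    RT is malformed and rejected.
    """
    out = trials.copy()
    has_resp = out["response"].notna()
    has_rt = out["rt_ms"].notna()
    bad = has_resp & ~has_rt
    if bad.any():
        rows = out.index[bad].tolist()[:5]
        raise MalformedRecordError(
            f"response present but rt_ms absent at row(s) {rows}"
        )
    out["is_miss"] = ~has_resp
    wrong = has_resp & (out["response"] != out["correct_response"])
    out["is_error"] = wrong | out["is_miss"]
    return out


_GROUP = ["participant_id", "session_index", "trial_type"]


def exclude_rt_outliers(
    trials: pd.DataFrame, config: CleaningConfig | None = None
) -> pd.DataFrame:
    """Flag correct-trial RT outliers by the raw-MAD criterion.

    Adds a boolean ``rt_outlier`` column.  Only correct (non-error) trials
    enter the RT statistics and only they can be flagged.  Groups with fewer
    than three correct trials are left unfiltered (logged).
    """
    config = config or CleaningConfig()
    out = trials.copy()
    out["rt_outlier"] = False
    correct_rt = out.loc[~out["is_error"], "rt_ms"]

    grouped = correct_rt.groupby([out[c] for c in _GROUP], sort=False)
    med = grouped.transform("median")
    dev = (correct_rt - med).abs()
    mad = dev.groupby([out[c] for c in _GROUP], sort=False).transform("median")
    size = grouped.transform("size")

    small = size < MIN_TRIALS_FOR_MAD
    if small.any():
        n_small = out.loc[small.index[small], _GROUP].drop_duplicates().shape[0]
        logger.warning(
            "%d group(s) with fewer than %d correct trials: RT filter skipped there",
            n_small, MIN_TRIALS_FOR_MAD,
        )
    flag = (dev > config.mad_multiplier * mad) & (mad > 0) & ~small
    out.loc[flag.index[flag], "rt_outlier"] = True
    return out


def _binom_tail(k: np.ndarray | int, n: np.ndarray | int, p: float) -> np.ndarray:
    """Exact P(X > k) for X ~ Binomial(n, p)."""
    return stats.binom.sf(k, n, p)


def exclude_below_chance(
    trials: pd.DataFrame, config: CleaningConfig | None = None
) -> pd.DataFrame:
    """Per-participant inclusion decision from the exact binomial rule.

    Accuracy is evaluated per session x trial type over *all* trials of that
    type (misses count as errors).  A participant is excluded when
    ``P(X > n_correct) > below_chance_crit`` for any evaluated cell, where
    ``X ~ Binomial(n_trials, chance_p)``.  With
    ``below_chance_pool_sessions`` the two sessions are pooled first.

    Returns one row per evaluated cell with ``n_trials``, ``n_correct``,
    ``p_exceed`` and ``excluded``; the participant-level decision is the OR
    over the participant's rows.
    """
    config = config or CleaningConfig()
    group = (
        ["participant_id", "trial_type"]
        if config.below_chance_pool_sessions
        else ["participant_id", "session_index", "trial_type"]
    )
    agg = (
        trials.assign(correct=~trials["is_error"])
        .groupby(group, sort=True)
        .agg(n_trials=("correct", "size"), n_correct=("correct", "sum"))
        .reset_index()
    )
    if (agg["n_trials"] == 0).any() or agg.empty:
        raise ValueError("below-chance rule undefined: a cell has no trials")
    agg["p_exceed"] = _binom_tail(
        agg["n_correct"].to_numpy(), agg["n_trials"].to_numpy(), config.chance_p
    )
    agg["excluded"] = agg["p_exceed"] > config.below_chance_crit
    return agg


def min_surviving_accuracy(
    n_trials: int = 80,
    chance_p: float = 0.25,
    crit: float = 0.01,
) -> float:
    """Smallest accuracy (%) that survives the below-chance rule.

    Scans k = 0..n with the exact binomial survivor function and returns
    100 * k_min / n for the smallest k with P(X > k) <= crit.
    """
    k = np.arange(n_trials + 1)
    ok = _binom_tail(k, n_trials, chance_p) <= crit
    if not ok.any():
        raise ValueError("no accuracy level survives the criterion")
    return 100.0 * k[ok][0] / n_trials


def winsorize_scores(
    scores: np.ndarray | pd.Series,
    config: CleaningConfig | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Replace scores beyond mean +- winsor_sd * SD with the boundary value.

    Mean and sample (n-1) SD are computed once from the original vector;
    replacement is a single pass.  Vectors with n < 2 are returned
    unchanged with a warning.  Returns the adjusted vector and a log frame
    with one row per replacement (index, original, replaced).
    """
    config = config or CleaningConfig()
    x = np.asarray(scores, dtype=float)
    empty_log = pd.DataFrame(columns=["index", "original", "replaced"])
    if x.size < 2:
        logger.warning("winsorize_scores: n=%d < 2, returned unchanged", x.size)
        return x.copy(), empty_log
    mean = x.mean()
    sd = x.std(ddof=1)
    lo, hi = mean - config.winsor_sd * sd, mean + config.winsor_sd * sd
    adjusted = np.clip(x, lo, hi)
    changed = np.flatnonzero(adjusted != x)
    log = pd.DataFrame(
        {"index": changed, "original": x[changed], "replaced": adjusted[changed]}
    )
    return adjusted, log


def clean_trials(
    trials: pd.DataFrame, config: CleaningConfig | None = None
) -> tuple[pd.DataFrame, CleaningReport]:
    """Run the trial-level cleaning chain and drop excluded participants.

    Returns the cleaned trial table (flags finalized, ``rt_outlier`` added,
    below-chance participants removed from both sessions) and a
    :class:`CleaningReport`.  Winsorization happens later, at the score
    level (see :mod:`countstroop.scoring`), and its log is appended to the
    report there.
    """
    config = config or CleaningConfig()
    marked = mark_errors_and_misses(trials)
    flagged = exclude_rt_outliers(marked, config)

    counts = (
        flagged.groupby(_GROUP, sort=True)
        .agg(
            n_trials=("is_error", "size"),
            n_misses=("is_miss", "sum"),
            n_errors=("is_error", "sum"),
            n_rt_outliers=("rt_outlier", "sum"),
        )
        .reset_index()
    )
    counts["n_rt_retained"] = (
        counts["n_trials"] - counts["n_errors"] - counts["n_rt_outliers"]
    )

    chance = exclude_below_chance(flagged, config)
    excluded = sorted(
        chance.loc[chance["excluded"], "participant_id"].unique().tolist()
    )
    if excluded:
        logger.info("below-chance exclusion of participant(s): %s", excluded)
    kept = flagged[~flagged["participant_id"].isin(excluded)].reset_index(drop=True)

    report = CleaningReport(
        trial_counts=counts,
        below_chance=chance,
        excluded_participants=excluded,
    )
    return kept, report
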