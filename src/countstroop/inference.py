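"""Frequentist inference for fully within-subject factorial designs.

Implements, from first principles, the repeated-measures ANOVA used for the
2 x 2 (alcohol x trial type) design and its generalization to any fully
crossed within design with one observation per subject and cell (needed for
the 2 x 4 quantile, 2 x 4 button and 2 x 2 x 2 sequential analyses):

* complete sum-of-squares decomposition over every subset of
  {subject, factors} via the Moebius (inclusion-exclusion) expansion of the
  marginal means;
* each within effect tested against its own subject interaction,
  ``F = MS_effect / MS_effect_x_subject``;
* generalized eta-squared with the denominator pooling the effect SS,
  the subject SS and *all* subject-related error SS — the convention for
  designs in which every factor is manipulated.

Also provides estimated marginal means (equal to cell means in this
balanced setting) and the sensitivity power analysis for the paired t-test,
which is algebraically equivalent to a 2-level within-factor F-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .generator import ALCOHOL, CONGRUENT, INCONGRUENT, PLACEBO

__all__ = [
    "AnovaResult",
    "EmmTable",
    "SensitivityResult",
    "rm_anova_within",
    "rm_anova_2x2",
    "estimated_marginal_means",
    "power_paired_t",
    "sensitivity_d",
    "ss_decomposition",
]


def ss_decomposition(y: np.ndarray) -> dict[tuple[int, ...], float]:
    """Sum of squares for every effect subset of a complete factorial array.

    ``y`` has the subject on axis 0 and one within factor per further axis,
    one observation per cell.  Keys are tuples of axis indices; ``()`` is
    the intercept (N * grand_mean**2).  The subset SS sum over all
    non-empty subsets equals the total centered SS.
    """
    axes = tuple(range(y.ndim))
    n_total = y.size
    marginal: dict[tuple[int, ...], np.ndarray] = {}
    for r in range(len(axes) + 1):
        for subset in combinations(axes, r):
            other = tuple(a for a in axes if a not in subset)
            marginal[subset] = (
                y.mean(axis=other, keepdims=True) if other else y.astype(float)
            )
    ss: dict[tuple[int, ...], float] = {}
    for subset, m in marginal.items():
        effect = np.zeros_like(m)
        for r in range(len(subset) + 1):
            for sub in combinations(subset, r):
                effect = effect + (-1) ** (len(subset) - len(sub)) * marginal[sub]
        replicates = n_total / effect.size
        ss[subset] = float(replicates * np.sum(effect**2))
    return ss


@dataclass
class AnovaResult:
    """Repeated-measures ANOVA table for a fully within design."""

    table: pd.DataFrame  # rows: intercept + effects; F, df_num, df_den, p, ges
    n_subjects: int
    ss: dict[str, float]

    def effect(self, name: str) -> pd.Series:
        row = self.table[self.table["effect"] == name]
        if row.empty:
            raise KeyError(f"no effect named {name!r}")
        return row.iloc[0]


def _anova_from_array(y: np.ndarray, factor_names: list[str]) -> AnovaResult:
    n = y.shape[0]
    if n < 2:
        raise ValueError("at least 2 subjects required")
    ss = ss_decomposition(y)
    subject_axis = 0
    factor_axes = tuple(range(1, y.ndim))

    ss_subject = ss[(subject_axis,)]
    error_ss_total = sum(
        ss[tuple(sorted((subject_axis,) + subset))]
        for r in range(1, len(factor_axes) + 1)
        for subset in combinations(factor_axes, r)
    )
    ges_denom_base = ss_subject + error_ss_total

    rows = []
    # intercept, tested against the subject term
    ss_int = ss[()]
    ms_sub = ss_subject / (n - 1)
    f_int = np.inf if ms_sub == 0 else ss_int / ms_sub
    if ss_int == 0:
        f_int = 0.0
    rows.append(
        {
            "effect": "intercept",
            "F": f_int,
            "df_num": 1,
            "df_den": n - 1,
            "p": float(stats.f.sf(f_int, 1, n - 1)) if np.isfinite(f_int) else 0.0,
            "ges": ss_int / (ss_int + ges_denom_base) if ss_int > 0 else 0.0,
        }
    )
    for r in range(1, len(factor_axes) + 1):
        for subset in combinations(factor_axes, r):
            name = ":".join(factor_names[a - 1] for a in subset)
            df_num = int(np.prod([y.shape[a] - 1 for a in subset]))
            df_den = df_num * (n - 1)
            ss_eff = ss[subset]
            ss_err = ss[tuple(sorted((subject_axis,) + subset))]
            if ss_eff == 0:
                f = 0.0
                p = 1.0
            elif ss_err == 0:
                f = np.inf
                p = 0.0
            else:
                f = (ss_eff / df_num) / (ss_err / df_den)
                p = float(stats.f.sf(f, df_num, df_den))
            denom = ss_eff + ges_denom_base
            rows.append(
                {
                    "effect": name,
                    "F": f,
                    "df_num": df_num,
                    "df_den": df_den,
                    "p": p,
                    "ges": ss_eff / denom if denom > 0 else 0.0,
                }
            )
    named_ss = {"intercept": ss_int, "subject": ss_subject}
    for subset, value in ss.items():
        if not subset or subset == (0,):
            continue
        parts = [
            "subject" if a == 0 else factor_names[a - 1] for a in subset
        ]
        named_ss[":".join(parts)] = value
    return AnovaResult(table=pd.DataFrame(rows), n_subjects=n, ss=named_ss)


def _complete_array(
    data: pd.DataFrame, dv: str, subject: str, within: list[str]
) -> tuple[np.ndarray, list[list]]:
    """Pivot long data to a (subjects x levels...) array, enforcing balance."""
    levels = [sorted(data[subject].unique())] + [
        sorted(data[w].unique()) for w in within
    ]
    indexed = data.set_index([subject] + within)[dv]
    dup = indexed.index.duplicated()
    if dup.any():
        raise ValueError(
            "multiple observations per subject x cell; aggregate first "
            f"(e.g. {indexed.index[dup][0]})"
        )
    full = pd.MultiIndex.from_product(levels, names=[subject] + within)
    aligned = indexed.reindex(full)
    if aligned.isna().any():
        missing = aligned[aligned.isna()].index.get_level_values(0).unique().tolist()
        raise ValueError(f"incomplete cases for subject(s): {missing}")
    shape = tuple(len(lv) for lv in levels)
    return aligned.to_numpy().reshape(shape), levels


def rm_anova_within(
    data: pd.DataFrame,
    dv: str,
    subject: str = "participant_id",
    within: list[str] | None = None,
) -> AnovaResult:
    """Fully within-subject RM-ANOVA on long-format data.

    Requires complete balanced data: exactly one observation per subject x
    cell (raises naming offenders otherwise).  Sphericity corrections are
    not applied; for 2-level factors they are vacuous, and the supplemental
    analyses follow the same uncorrected convention.
    """
    if not within:
        raise ValueError("at least one within factor is required")
    y, _levels = _complete_array(data, dv, subject, list(within))
    return _anova_from_array(y, list(within))


def _score_array(score_table: pd.DataFrame, measure: str) -> np.ndarray:
    """(n, 2, 2) array: subject x condition(alcohol, placebo) x trial type
    (incongruent, congruent) from the wide score table."""
    cols = [f"{measure}_incongruent", f"{measure}_congruent"]
    wide = score_table.pivot(
        index="participant_id", columns="condition", values=cols
    )
    expected = [(c, cond) for c in cols for cond in (ALCOHOL, PLACEBO)]
    missing_cols = [c for c in expected if c not in wide.columns]
    if missing_cols:
        raise ValueError(f"score table lacks cells: {missing_cols}")
    incomplete = wide.index[wide[expected].isna().any(axis=1)].tolist()
    if incomplete:
        raise ValueError(f"incomplete cases for subject(s): {incomplete}")
    n = len(wide)
    y = np.empty((n, 2, 2))
    y[:, 0, 0] = wide[(cols[0], ALCOHOL)].to_numpy()
    y[:, 0, 1] = wide[(cols[1], ALCOHOL)].to_numpy()
    y[:, 1, 0] = wide[(cols[0], PLACEBO)].to_numpy()
    y[:, 1, 1] = wide[(cols[1], PLACEBO)].to_numpy()
    return y


def rm_anova_2x2(score_table: pd.DataFrame, measure: str) -> AnovaResult:
    """2 x 2 (alcohol x trial type) within-subject ANOVA on one measure."""
    y = _score_array(score_table, measure)
    return _anova_from_array(y, ["alcohol", "trial_type"])


@dataclass
class EmmTable:
    """Estimated marginal means for the 2 x 2 design (= cell means here)."""

    cells: pd.DataFrame  # condition x trial_type -> emm
    alcohol_diff: float  # alcohol - placebo
    trialtype_diff: float  # incongruent - congruent
    measure: str


def estimated_marginal_means(score_table: pd.DataFrame, measure: str) -> EmmTable:
    """Cell and factor-level EMMs with the two factor differences.

    In a complete balanced within design the model-based marginal means
    coincide with arithmetic cell means across participants.
    """
    y = _score_array(score_table, measure)
    cell_means = y.mean(axis=0)  # (condition, trial_type)
    cells = pd.DataFrame(
        {
            "condition": [ALCOHOL, ALCOHOL, PLACEBO, PLACEBO],
            "trial_type": [INCONGRUENT, CONGRUENT, INCONGRUENT, CONGRUENT],
            "emm": [
                cell_means[0, 0],
                cell_means[0, 1],
                cell_means[1, 0],
                cell_means[1, 1],
            ],
        }
    )
    return EmmTable(
        cells=cells,
        alcohol_diff=float(cell_means[0].mean() - cell_means[1].mean()),
        trialtype_diff=float(cell_means[:, 0].mean() - cell_means[:, 1].mean()),
        measure=measure,
    )


@dataclass
class SensitivityResult:
    """Minimal detectable effect size for a paired two-tailed t-test."""

    n: int
    alpha: float
    power: float
    d: float


def power_paired_t(d: float, n: int, alpha: float = 0.05) -> float:
    """Exact power of the two-tailed paired t-test at effect size d.

    Uses the noncentral t distribution with df = n - 1 and noncentrality
    d * sqrt(n).
    """
    df = n - 1
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    nc = d * np.sqrt(n)
    power = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    if not np.isfinite(power):
        # the noncentral-t tail routine loses accuracy only deep in the
        # saturated region, where the rejection probability is 1 to within
        # double precision
        power = 1.0 if nc > tcrit else 0.0
    return float(power)


def sensitivity_d(
    n: int, alpha: float = 0.05, power: float = 0.95
) -> SensitivityResult:
    """Smallest Cohen's d detectable with the requested power.

    Root-finds the noncentral-t power function; the returned d reproduces
    the requested power to better than 1e-6.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if power <= alpha:
        raise ValueError("power must exceed alpha for a positive solution")
    d = optimize.brentq(
        lambda x: power_paired_t(x, n, alpha) - power, 1e-9, 50.0, xtol=1e-12
    )
    return SensitivityResult(n=n, alpha=alpha, power=power, d=float(d))
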