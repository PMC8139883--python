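"""Tests of the within-subject ANOVA, EMMs and sensitivity analysis.

The RM-ANOVA is checked against (a) a brute-force textbook sum-of-squares
oracle written independently here with explicit loops, (b) statsmodels'
AnovaRM, and (c) the paired-t algebraic identity F = t^2 for 2-level main
effects.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.anova import AnovaRM

import countstroop as cs


def _random_2x2_long(n, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        s = rng.normal(0, 1)
        for a in ("alcohol", "placebo"):
            for t in ("incongruent", "congruent"):
                y = (
                    10
                    + s
                    + 0.6 * (a == "alcohol")
                    + 1.1 * (t == "incongruent")
                    + 0.3 * (a == "alcohol") * (t == "incongruent")
                    + rng.normal(0, 0.8)
                )
                rows.append(
                    {"participant_id": f"s{i}", "alcohol": a, "trial_type": t, "y": y}
                )
    return pd.DataFrame(rows)


def _brute_force_2x2(df):
    """Textbook SS decomposition with explicit loops (independent oracle)."""
    subjects = sorted(df["participant_id"].unique())
    n = len(subjects)
    y = np.zeros((n, 2, 2))
    for i, s in enumerate(subjects):
        for j, a in enumerate(["alcohol", "placebo"]):
            for k, t in enumerate(["incongruent", "congruent"]):
                y[i, j, k] = df.query(
                    "participant_id == @s and alcohol == @a and trial_type == @t"
                )["y"].iloc[0]
    grand = y.mean()
    ss = {}
    ss["subject"] = 4 * sum((y[i].mean() - grand) ** 2 for i in range(n))
    ss["A"] = 2 * n * sum((y[:, j].mean() - grand) ** 2 for j in range(2))
    ss["B"] = 2 * n * sum((y[:, :, k].mean() - grand) ** 2 for k in range(2))
    ss["AB"] = n * sum(
        (y[:, j, k].mean() - y[:, j].mean() - y[:, :, k].mean() + grand) ** 2
        for j in range(2)
        for k in range(2)
    )
    ss["As"] = 2 * sum(
        (y[i, j].mean() - y[i].mean() - y[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(2)
    )
    ss["Bs"] = 2 * sum(
        (y[i, :, k].mean() - y[i].mean() - y[:, :, k].mean() + grand) ** 2
        for i in range(n)
        for k in range(2)
    )
    total = ((y - grand) ** 2).sum()
    ss["ABs"] = total - sum(
        ss[k] for k in ("subject", "A", "B", "AB", "As", "Bs")
    )
    f = {
        "A": (ss["A"] / 1) / (ss["As"] / (n - 1)),
        "B": (ss["B"] / 1) / (ss["Bs"] / (n - 1)),
        "AB": (ss["AB"] / 1) / (ss["ABs"] / (n - 1)),
    }
    denom_err = ss["subject"] + ss["As"] + ss["Bs"] + ss["ABs"]
    ges = {k: ss[k] / (ss[k] + denom_err) for k in ("A", "B", "AB")}
    return f, ges


class TestAnovaOracles:
    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7, 8])
    def test_matches_brute_force_ss_oracle(self, n):
        df = _random_2x2_long(n, seed=n)
        res = cs.rm_anova_within(
            df, dv="y", subject="participant_id", within=["alcohol", "trial_type"]
        )
        f, ges = _brute_force_2x2(df)
        for effect, key in [
            ("alcohol", "A"),
            ("trial_type", "B"),
            ("alcohol:trial_type", "AB"),
        ]:
            row = res.effect(effect)
            assert row["F"] == pytest.approx(f[key], abs=1e-8, rel=1e-10)
            assert row["ges"] == pytest.approx(ges[key], abs=1e-10)
            assert row["df_num"] == 1 and row["df_den"] == n - 1

    @pytest.mark.parametrize("n", [5, 9])
    def test_matches_statsmodels_anovarm(self, n):
        df = _random_2x2_long(n, seed=100 + n)
        mine = cs.rm_anova_within(
            df, dv="y", subject="participant_id", within=["alcohol", "trial_type"]
        )
        ref = AnovaRM(
            df, "y", "participant_id", within=["alcohol", "trial_type"]
        ).fit().anova_table
        for effect, key in [
            ("alcohol", "alcohol"),
            ("trial_type", "trial_type"),
            ("alcohol:trial_type", "alcohol:trial_type"),
        ]:
            assert mine.effect(effect)["F"] == pytest.approx(
                ref.loc[key, "F Value"], rel=1e-10
            )
            assert mine.effect(effect)["p"] == pytest.approx(
                ref.loc[key, "Pr > F"], abs=1e-12
            )

    def test_generalized_matches_statsmodels_2x4(self):
        rng = np.random.default_rng(42)
        rows = []
        for i in range(7):
            s = rng.normal()
            for a in ("x", "y"):
                for q in (1, 2, 3, 4):
                    rows.append(
                        {
                            "participant_id": f"s{i}",
                            "cond": a,
                            "quantile": q,
                            "y": s + 0.4 * q + rng.normal(),
                        }
                    )
        df = pd.DataFrame(rows)
        mine = cs.rm_anova_within(
            df, dv="y", subject="participant_id", within=["cond", "quantile"]
        )
        ref = AnovaRM(
            df, "y", "participant_id", within=["cond", "quantile"]
        ).fit().anova_table
        assert mine.effect("quantile")["F"] == pytest.approx(
            ref.loc["quantile", "F Value"], rel=1e-10
        )
        assert mine.effect("quantile")["df_num"] == 3
        assert mine.effect("cond:quantile")["F"] == pytest.approx(
            ref.loc["cond:quantile", "F Value"], rel=1e-10
        )

    def test_main_effect_f_equals_squared_paired_t(self, score_table):
        """For a 2-level within factor, F is exactly the squared paired t
        on the per-participant contrast scores."""
        res = cs.rm_anova_2x2(score_table, "rt")
        wide = score_table.pivot(index="participant_id", columns="condition")
        # alcohol contrast: participant means under alcohol vs placebo
        alc = (
            wide[("rt_incongruent", "alcohol")] + wide[("rt_congruent", "alcohol")]
        ) / 2
        pla = (
            wide[("rt_incongruent", "placebo")] + wide[("rt_congruent", "placebo")]
        ) / 2
        t_stat = stats.ttest_rel(alc, pla).statistic
        assert res.effect("alcohol")["F"] == pytest.approx(t_stat**2, rel=1e-10)
        # trial-type contrast
        inc = (
            wide[("rt_incongruent", "alcohol")] + wide[("rt_incongruent", "placebo")]
        ) / 2
        con = (
            wide[("rt_congruent", "alcohol")] + wide[("rt_congruent", "placebo")]
        ) / 2
        t_stat = stats.ttest_rel(inc, con).statistic
        assert res.effect("trial_type")["F"] == pytest.approx(t_stat**2, rel=1e-10)

    def test_no_within_variance_gives_zero_f(self):
        rows = []
        for i, c in enumerate([3.0, 5.0, 9.0, 1.0]):
            for a in ("a1", "a2"):
                for b in ("b1", "b2"):
                    rows.append(
                        {"participant_id": f"s{i}", "A": a, "B": b, "y": c}
                    )
        res = cs.rm_anova_within(
            pd.DataFrame(rows), dv="y", subject="participant_id", within=["A", "B"]
        )
        for effect in ("A", "B", "A:B"):
            assert res.effect(effect)["F"] == 0.0
            assert res.effect(effect)["p"] == 1.0

    def test_incomplete_cases_rejected(self):
        df = _random_2x2_long(4, seed=0).iloc[:-1]
        with pytest.raises(ValueError, match="s3"):
            cs.rm_anova_within(
                df, dv="y", subject="participant_id", within=["alcohol", "trial_type"]
            )


class TestEmm:
    def test_cell_emms_are_cell_means(self, score_table):
        emm = cs.estimated_marginal_means(score_table, "rt")
        alc_inc = score_table.loc[
            score_table["condition"] == "alcohol", "rt_incongruent"
        ].mean()
        got = emm.cells.query(
            "condition == 'alcohol' and trial_type == 'incongruent'"
        )["emm"].iloc[0]
        assert got == pytest.approx(alc_inc)

    def test_symmetric_data_zero_difference(self):
        rows = []
        for i in range(5):
            for cond in ("alcohol", "placebo"):
                rows.append(
                    {
                        "participant_id": f"s{i}",
                        "condition": cond,
                        "rt_incongruent": 500.0 + i,
                        "rt_congruent": 500.0 + i,
                        "er_incongruent": 0.0,
                        "er_congruent": 0.0,
                        "ies_incongruent": 500.0 + i,
                        "ies_congruent": 500.0 + i,
                    }
                )
        emm = cs.estimated_marginal_means(pd.DataFrame(rows), "rt")
        assert emm.alcohol_diff == 0.0
        assert emm.trialtype_diff == 0.0


class TestSensitivity:
    def test_reference_value(self):
        """n=40, two-tailed alpha .05, power .95 -> d = 0.58."""
        res = cs.sensitivity_d(40, alpha=0.05, power=0.95)
        assert round(res.d, 2) == 0.58

    def test_power_roundtrip(self):
        for n, power in [(40, 0.95), (40, 0.80), (12, 0.90)]:
            res = cs.sensitivity_d(n, alpha=0.05, power=power)
            assert cs.power_paired_t(res.d, n, 0.05) == pytest.approx(
                power, abs=1e-6
            )

    def test_independent_power_oracle_at_080(self):
        """Root of a directly-coded noncentral-t power curve at power .80."""
        tcrit = stats.t.ppf(0.975, 39)
        grid = np.linspace(0.3, 0.6, 3001)
        power = stats.nct.sf(tcrit, 39, grid * np.sqrt(40)) + stats.nct.cdf(
            -tcrit, 39, grid * np.sqrt(40)
        )
        d_oracle = grid[np.argmin(np.abs(power - 0.80))]
        assert cs.sensitivity_d(40, power=0.80).d == pytest.approx(
            d_oracle, abs=1e-3
        )

    def test_monotone_in_n_and_power(self):
        assert cs.sensitivity_d(160).d < cs.sensitivity_d(40).d
        assert cs.sensitivity_d(40, power=0.80).d < cs.sensitivity_d(40, power=0.95).d

    def test_power_not_exceeding_alpha_rejected(self):
        with pytest.raises(ValueError):
            cs.sensitivity_d(40, alpha=0.05, power=0.04)
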