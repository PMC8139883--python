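"""Tests of the delta-plot, conflict-adaptation and button analyses."""

import numpy as np
import pandas as pd
import pytest

import countstroop as cs
from countstroop.supplemental import _with_previous_type


def _make_trials(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "condition", "session_index", "trial_index",
            "trial_type", "correct_response", "rt_ms", "is_error", "rt_outlier",
        ],
    )


def _two_type_trials(n_per_cell, rt_fn, participants=("p1", "p2", "p3", "p4")):
    """Trials for both conditions/types with RTs from rt_fn(cell_args, i)."""
    rows = []
    for p_i, pid in enumerate(participants):
        for cond in ("alcohol", "placebo"):
            session = 1 if cond == "alcohol" else 2
            idx = 0
            for ttype in ("incongruent", "congruent"):
                for i in range(n_per_cell):
                    idx += 1
                    rows.append(
                        [pid, cond, session, idx, ttype, (i % 4) + 1,
                         rt_fn(p_i, cond, ttype, i), False, False]
                    )
    return _make_trials(rows)


class TestDeltaPlot:
    def test_equal_count_bins(self):
        for n in (8, 9, 10, 11, 23):
            rts = np.arange(n, dtype=float) + 300
            bins = np.array_split(np.sort(rts), 4)
            sizes = [len(b) for b in bins]
            assert max(sizes) - min(sizes) <= 1
            # remainder goes to the earliest bins
            assert sizes == sorted(sizes, reverse=True)

    def test_pure_shift_gives_constant_interference(self):
        """incongruent = congruent + c: every quantile shows exactly c."""
        rng = np.random.default_rng(0)
        base = {}

        def rt_fn(p, cond, ttype, i):
            key = (p, cond, i)
            if key not in base:
                base[key] = 400 + 100 * rng.random()
            return base[key] + (35.0 if ttype == "incongruent" else 0.0)

        trials = _two_type_trials(24, rt_fn)
        res = cs.delta_plot(trials)
        assert np.allclose(res.scores["interference_ms"], 35.0)

    def test_multiplicative_effect_grows_across_quantiles(self):
        """incongruent = 1.1 x congruent: interference increases with RT."""
        rng = np.random.default_rng(1)
        samples = {p: 400 + 150 * rng.random(40) for p in range(4)}

        def rt_fn(p, cond, ttype, i):
            rt = samples[p][i]
            return 1.1 * rt if ttype == "incongruent" else rt

        trials = _two_type_trials(40, rt_fn)
        res = cs.delta_plot(trials)
        for _, grp in res.scores.groupby(["participant_id", "condition"]):
            vals = grp.sort_values("quantile")["interference_ms"].to_numpy()
            assert np.all(np.diff(vals) > 0)

    def test_quantile_mean_of_interference_matches_total(self):
        """With counts divisible by 4, the mean across quantile bins equals
        the overall mean, so average per-quantile interference equals total
        interference."""
        rng = np.random.default_rng(2)

        def rt_fn(p, cond, ttype, i):
            return 450 + 80 * rng.random() + (30 if ttype == "incongruent" else 0)

        trials = _two_type_trials(32, rt_fn)
        res = cs.delta_plot(trials)
        per_q = res.scores.groupby(["participant_id", "condition"])[
            "interference_ms"
        ].mean()
        kept = trials
        cell = kept.groupby(["participant_id", "condition", "trial_type"])[
            "rt_ms"
        ].mean().unstack("trial_type")
        total = cell["incongruent"] - cell["congruent"]
        assert np.allclose(per_q.sort_index(), total.sort_index())

    def test_small_cells_dropped(self):
        rng = np.random.default_rng(3)

        def rt_fn(p, cond, ttype, i):
            return 450 + 50 * rng.random()

        trials = _two_type_trials(20, rt_fn)
        # p1 loses most incongruent-alcohol trials
        drop = trials[
            (trials["participant_id"] == "p1")
            & (trials["condition"] == "alcohol")
            & (trials["trial_type"] == "incongruent")
        ].index[5:]
        trials = trials.drop(drop)
        res = cs.delta_plot(trials)
        assert res.dropped_participants == ["p1"]
        assert "p1" not in res.scores["participant_id"].unique()

    def test_default_study_quantile_effect(self, clean_study):
        """The generator's scaled residual yields a strong quantile main
        effect and increasing mean interference from quantile 1 to 4."""
        res = cs.delta_plot(clean_study)
        assert res.anova.effect("quantile")["p"] < 0.001
        means = (
            res.cell_means.groupby("quantile")["interference_ms"].mean().to_numpy()
        )
        assert np.all(np.diff(means) > 0)


class TestGratton:
    def test_sequential_partition(self, study):
        """Exactly n-1 trials per session enter sequential classification."""
        seq = _with_previous_type(study)
        per_session = seq.groupby(["participant_id", "session_index"]).size()
        assert (per_session == 159).all()
        counts = seq.groupby(["previous_type", "trial_type"]).size()
        assert counts.sum() == len(seq)

    def test_previous_type_uses_presentation_order(self):
        rows = [
            ["p1", "placebo", 1, 1, "incongruent", 1, 500.0, True, False],
            ["p1", "placebo", 1, 2, "congruent", 2, 510.0, False, False],
            ["p1", "placebo", 1, 3, "incongruent", 3, 520.0, False, False],
        ]
        seq = _with_previous_type(_make_trials(rows))
        # the error trial still provides sequential context
        assert seq["previous_type"].tolist() == ["incongruent", "congruent"]

    def test_adaptation_recovered_from_default_generator(self, clean_study):
        """gratton_ms = 20 at default: the recovered conflict adaptation
        should be close on a single 40-participant study."""
        res = cs.gratton_analysis(clean_study)
        assert res.mean_adaptation_ms == pytest.approx(20.0, abs=10.0)
        assert res.anova.effect("previous_type:trial_type")["p"] < 0.05

    def test_null_adaptation_when_generator_effect_absent(self):
        cfg = cs.GeneratorConfig(gratton_ms=0.0, n_participants=20)
        vals = []
        for seed in range(6):
            study = cs.simulate_study(cfg, seed=seed)
            clean, _ = cs.clean_trials(study)
            vals.append(cs.gratton_analysis(clean).mean_adaptation_ms)
        assert np.mean(vals) == pytest.approx(0.0, abs=6.0)

    def test_reduces_to_2x2_machinery(self, clean_study):
        """The generalized ANOVA on 2x2x2 keeps df = (1, n-1) per effect."""
        res = cs.gratton_analysis(clean_study)
        for _, row in res.anova.table.iterrows():
            if row["effect"] == "intercept":
                continue
            assert row["df_num"] == 1
            assert row["df_den"] == res.anova.n_subjects - 1


class TestButtons:
    def test_design_balance_per_button(self):
        cfg = cs.GeneratorConfig()
        seq = cs.generate_trial_sequence(cfg, seed=13)
        counts = seq.groupby(["trial_type", "correct_response"]).size()
        assert (counts == 20).all()

    def test_injected_button_effect_detected(self):
        rng = np.random.default_rng(4)

        def rt_fn(p, cond, ttype, i):
            rt = 450 + 40 * rng.standard_normal()
            if ttype == "incongruent":
                rt += 40.0 if (i % 4) + 1 == 4 else 10.0
            return rt

        trials = _two_type_trials(40, rt_fn, participants=[f"p{i}" for i in range(8)])
        scores, anova = cs.button_analysis(trials)
        per_button = scores.groupby("button")["interference_ms"].mean()
        assert per_button[4] == pytest.approx(40.0, abs=8.0)
        assert per_button[per_button.index != 4].mean() == pytest.approx(10.0, abs=6.0)
        assert anova.effect("button")["p"] < 0.01

    def test_null_button_interaction_on_default_study(self, clean_study):
        """Button-independent generator effects: no alcohol x button effect."""
        _scores, anova = cs.button_analysis(clean_study)
        assert anova.effect("condition:button")["p"] > 0.001
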