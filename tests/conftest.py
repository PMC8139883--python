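"""Shared fixtures: one default study and a bank of replicate studies.

The replicate bank simulates 100 studies at the default configuration and
pushes each through the full cleaning/scoring pipeline once, so that the
parameter-recovery, Bayes-factor and conflict-adaptation checks can share
the cost.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import countstroop as cs

REPLICATE_BASE_SEED = 727
N_REPLICATES = 100


def run_study_pipeline(seed: int, config: cs.GeneratorConfig | None = None,
                       n_mc: int = 4000) -> dict[str, float]:
    """Simulate one study and run it through cleaning, scoring, inference."""
    config = config or cs.GeneratorConfig()
    study = cs.simulate_study(config, seed=seed)
    clean, _report = cs.clean_trials(study)
    cells = cs.compute_cell_summaries(clean)
    scores, _ = cs.winsorize_score_table(cs.compute_interference(cells))
    emm = cs.estimated_marginal_means(scores, "rt")
    anova = cs.rm_anova_2x2(scores, "rt")
    bf = cs.jzs_bayes_factors(scores, "rt", n_mc_samples=n_mc, seed=seed)
    gratton = cs.gratton_analysis(clean)
    return {
        "trialtype_diff": emm.trialtype_diff,
        "alcohol_diff": emm.alcohol_diff,
        "grand_er": float(cells["er"].mean()),
        "interaction_p": float(anova.effect("alcohol:trial_type")["p"]),
        "bf_full_vs_main": bf.bf_full_vs_main,
        "adaptation_ms": gratton.mean_adaptation_ms,
    }


@pytest.fixture(scope="session")
def default_config() -> cs.GeneratorConfig:
    return cs.GeneratorConfig()


@pytest.fixture(scope="session")
def study(default_config) -> pd.DataFrame:
    return cs.simulate_study(default_config, seed=11)


@pytest.fixture(scope="session")
def cleaned(study):
    return cs.clean_trials(study)


@pytest.fixture(scope="session")
def clean_study(cleaned) -> pd.DataFrame:
    return cleaned[0]


@pytest.fixture(scope="session")
def score_table(clean_study) -> pd.DataFrame:
    cells = cs.compute_cell_summaries(clean_study)
    scores, _log = cs.winsorize_score_table(cs.compute_interference(cells))
    return scores


@pytest.fixture(scope="session")
def replicate_stats() -> pd.DataFrame:
    """100 replicate default studies through the full pipeline."""
    seeds = np.random.SeedSequence(REPLICATE_BASE_SEED).generate_state(N_REPLICATES)
    seeds = (seeds % (2**31 - 1)).astype(int)
    return pd.DataFrame([run_study_pipeline(int(s)) for s in seeds])
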