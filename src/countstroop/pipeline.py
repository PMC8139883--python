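"""End-to-end pipeline: simulate -> preprocess -> score -> infer -> supplemental.

Each stage reads its inputs from, and writes its artifacts to, a single
output directory so that the CLI stages compose: running them one at a
time over the intermediate files produces byte-identical outputs to
running everything at once.  A ``run_info.json`` records the configuration
hash and seeds from which every numeric cell is reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .bayes import jzs_bayes_factors
from .config import RunConfig
from .generator import simulate_study
from .inference import estimated_marginal_means, rm_anova_2x2, sensitivity_d
from .io import read_trials, write_trials
from .preprocessing import clean_trials
from .scoring import (
    MEASURES,
    compute_cell_summaries,
    compute_interference,
    reliability_table,
    winsorize_score_table,
)
from .supplemental import button_analysis, delta_plot, gratton_analysis

__all__ = ["run_pipeline", "PipelineStageError", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "score", "infer", "supplemental", "report")


class PipelineStageError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""


def _write_run_info(config: RunConfig, out: Path) -> None:
    info = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
    }
    (out / "run_info.json").write_text(json.dumps(info, indent=2) + "\n")


def _outdir(config: RunConfig, out_dir: str | Path | None) -> Path:
    out = Path(out_dir) if out_dir is not None else Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_simulate(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    out = _outdir(config, out_dir)
    trials = simulate_study(config.generator)
    write_trials(trials, out / "trials.csv")
    _write_run_info(config, out)
    return out / "trials.csv"


def stage_preprocess(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    out = _outdir(config, out_dir)
    trials = read_trials(out / "trials.csv")
    cleaned, report = clean_trials(trials, config.cleaning)
    write_trials(cleaned, out / "clean_trials.csv", extra_columns=("rt_outlier",))
    report.trial_counts.to_csv(out / "cleaning_counts.csv", index=False)
    report.below_chance.to_csv(out / "below_chance.csv", index=False)
    text = report.to_text() + f"\nconfig_hash: {config.config_hash()}\n"
    (out / "cleaning_report.txt").write_text(text)
    return out / "clean_trials.csv"


def stage_score(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    out = _outdir(config, out_dir)
    cleaned = read_trials(out / "clean_trials.csv", extra_columns=("rt_outlier",))
    cells = compute_cell_summaries(cleaned)
    cells.to_csv(out / "cell_summaries.csv", index=False)
    raw_scores = compute_interference(cells)
    raw_scores.to_csv(out / "score_table_raw.csv", index=False)
    scores, winsor_log = winsorize_score_table(raw_scores, config.cleaning)
    scores.to_csv(out / "score_table.csv", index=False)
    winsor_log.to_csv(out / "winsor_log.csv", index=False)
    reliability_table(cleaned).to_csv(out / "reliability.csv", index=False)
    return out / "score_table.csv"


def _anova_report(anovas: dict[str, "pd.DataFrame"]) -> tuple[pd.DataFrame, str]:
    """Main-analysis table: effects as rows; F, p, ges per measure."""
    frames = []
    for measure, table in anovas.items():
        t = table.copy()
        t.insert(0, "measure", measure)
        frames.append(t)
    combined = pd.concat(frames, ignore_index=True)

    effects = anovas[next(iter(anovas))]["effect"].tolist()
    lines = ["Main 2x2 within-subject ANOVA (F, p, generalized eta-squared)", ""]
    header = f"{'effect':<24}" + "".join(
        f"{m.upper():>8}{'p':>9}{'ges':>7}" for m in anovas
    )
    lines.append(header)
    for effect in effects:
        row = f"{effect:<24}"
        for measure, table in anovas.items():
            e = table[table["effect"] == effect].iloc[0]
            row += f"{e['F']:>8.2f}{e['p']:>9.3f}{e['ges']:>7.3f}"
        lines.append(row)
    return combined, "\n".join(lines) + "\n"


def _bayes_report(bfs: dict[str, object]) -> tuple[pd.DataFrame, str]:
    rows = []
    lines = ["JZS Bayes factors (denominator: subject-only null)", ""]
    for measure, bf in bfs.items():
        lines.append(measure.upper())
        for model, value in bf.bf_vs_null.items():
            err = bf.error_vs_null[model]
            rows.append(
                {
                    "measure": measure,
                    "model": model,
                    "denominator": "null",
                    "bf": value,
                    "proportional_error": err,
                }
            )
            lines.append(f"  {model:<34} {value:>12.4g}  +-{err:8.2%}")
        rows.append(
            {
                "measure": measure,
                "model": "trial_type+alcohol+interaction",
                "denominator": "trial_type+alcohol",
                "bf": bf.bf_full_vs_main,
                "proportional_error": bf.error_full_vs_main,
            }
        )
        lines.append(
            f"  {'full vs main effects':<34} {bf.bf_full_vs_main:>12.4g}"
            f"  +-{bf.error_full_vs_main:8.2%}"
        )
        lines.append("")
    return pd.DataFrame(rows), "\n".join(lines)


def stage_infer(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    out = _outdir(config, out_dir)
    scores = pd.read_csv(out / "score_table.csv")
    inf = config.inference

    anovas = {m: rm_anova_2x2(scores, m).table for m in MEASURES}
    anova_csv, anova_txt = _anova_report(anovas)
    anova_csv.to_csv(out / "anova_table.csv", index=False)

    emm_rows = []
    for m in MEASURES:
        emm = estimated_marginal_means(scores, m)
        cells = emm.cells.assign(measure=m)
        emm_rows.append(cells)
        emm_rows.append(
            pd.DataFrame(
                {
                    "condition": ["difference", "difference"],
                    "trial_type": ["alcohol-placebo", "incongruent-congruent"],
                    "emm": [emm.alcohol_diff, emm.trialtype_diff],
                    "measure": [m, m],
                }
            )
        )
    pd.concat(emm_rows, ignore_index=True).to_csv(out / "emm_table.csv", index=False)

    n = scores["participant_id"].nunique()
    sens = sensitivity_d(n, alpha=inf.alpha, power=inf.power)
    anova_txt += (
        f"\nSensitivity (paired two-tailed t, n={n}, alpha={inf.alpha}, "
        f"power={inf.power}): minimal detectable d = {sens.d:.2f}\n"
        f"config_hash: {config.config_hash()}\n"
    )
    (out / "anova_table.txt").write_text(anova_txt)

    bfs = {
        m: jzs_bayes_factors(
            scores,
            m,
            n_mc_samples=inf.n_mc_samples,
            seed=inf.seed,
            rscale_fixed=inf.rscale_fixed,
            rscale_random=inf.rscale_random,
        )
        for m in MEASURES
    }
    bayes_csv, bayes_txt = _bayes_report(bfs)
    bayes_csv.to_csv(out / "bayes_table.csv", index=False)
    (out / "bayes_table.txt").write_text(
        bayes_txt + f"config_hash: {config.config_hash()}\n"
    )
    return out / "anova_table.csv"


def stage_supplemental(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    out = _outdir(config, out_dir)
    cleaned = read_trials(out / "clean_trials.csv", extra_columns=("rt_outlier",))

    dp = delta_plot(cleaned)
    dp.cell_means.to_csv(out / "delta_plot.csv", index=False)
    gr = gratton_analysis(cleaned)
    gr.adaptation.to_csv(out / "gratton.csv", index=False)
    button_scores, button_anova = button_analysis(cleaned)
    button_scores.to_csv(out / "button.csv", index=False)

    lines = ["Supplemental masking checks", ""]
    q = dp.anova.effect("quantile")
    lines.append(
        f"delta plot quantile main effect: F({q['df_num']},{q['df_den']}) = "
        f"{q['F']:.2f}, p = {q['p']:.3g}"
    )
    qa = dp.anova.effect("condition:quantile")
    lines.append(
        f"alcohol x quantile interaction: F({qa['df_num']},{qa['df_den']}) = "
        f"{qa['F']:.2f}, p = {qa['p']:.3g}"
    )
    g = gr.anova.effect("previous_type:trial_type")
    lines.append(
        f"conflict adaptation (previous x current): F({g['df_num']},{g['df_den']})"
        f" = {g['F']:.2f}, p = {g['p']:.3g}; "
        f"mean adaptation = {gr.mean_adaptation_ms:.1f} ms"
    )
    b = button_anova.effect("condition:button")
    lines.append(
        f"alcohol x button interaction: F({b['df_num']},{b['df_den']}) = "
        f"{b['F']:.2f}, p = {b['p']:.3g}"
    )
    lines.append(f"config_hash: {config.config_hash()}")
    (out / "supplemental.txt").write_text("\n".join(lines) + "\n")
    return out / "supplemental.txt"


def stage_report(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Assemble the one-file summary from the per-stage artifacts."""
    out = _outdir(config, out_dir)
    parts = []
    for name in (
        "cleaning_report.txt",
        "anova_table.txt",
        "bayes_table.txt",
        "supplemental.txt",
    ):
        path = out / name
        if not path.exists():
            raise PipelineStageError(f"[report] missing artifact {name}; run earlier stages")
        parts.append(path.read_text())
    rel = pd.read_csv(out / "reliability.csv")
    rel_lines = ["Split-half reliability (Spearman-Brown adjusted)", ""]
    for _, r in rel.iterrows():
        rel_lines.append(
            f"  {r['measure']:<4} {r['condition']:<9} r = {r['split_half_r']:.2f}"
            f"  alpha = {r['cronbach_alpha']:.2f}"
        )
    parts.append("\n".join(rel_lines) + "\n")
    text = ("\n" + "-" * 60 + "\n").join(parts)
    (out / "report.txt").write_text(text)
    return out / "report.txt"


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "score": stage_score,
    "infer": stage_infer,
    "supplemental": stage_supplemental,
    "report": stage_report,
}


@dataclass
class PipelineResult:
    out_dir: Path
    config_hash: str
    artifacts: dict[str, Path]


def run_stage(stage: str, config: RunConfig, out_dir: str | Path | None = None) -> Path:
    if stage not in _STAGE_FUNCS:
        raise PipelineStageError(f"unknown stage {stage!r}; choose from {STAGES}")
    try:
        return _STAGE_FUNCS[stage](config, out_dir)
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-tagged failure contract
        raise PipelineStageError(f"[{stage}] {exc}") from exc


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run every stage in order on one output directory."""
    out = _outdir(config, out_dir)
    for stage in STAGES:
        logger.info("running stage %s", stage)
        run_stage(stage, config, out)
    artifacts = {
        name: out / name
        for name in (
            "trials.csv",
            "clean_trials.csv",
            "cleaning_report.txt",
            "cell_summaries.csv",
            "score_table.csv",
            "reliability.csv",
            "anova_table.csv",
            "anova_table.txt",
            "bayes_table.csv",
            "bayes_table.txt",
            "delta_plot.csv",
            "gratton.csv",
            "button.csv",
            "report.txt",
        )
    }
    return PipelineResult(
        out_dir=out, config_hash=config.config_hash(), artifacts=artifacts
    )
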