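"""Default-prior (JZS) Bayes factors for within-subject factorial designs.

The model follows the default-prior ANOVA construction: for data
``y = mu * 1 + sum_b X_b theta_b + eps`` with ``eps ~ N(0, sigma^2 I)``,
each effect block b (subject; each factor; each interaction) carries
standardized effects ``theta_b ~ N(0, g_b sigma^2 I)`` on orthonormal
sum-to-zero contrast columns, with independent scaled inverse-chi-squared
priors ``g_b ~ InvGamma(1/2, r_b^2 / 2)`` (i.e. Cauchy priors on the
standardized effects; default scales 0.5 for fixed effects, 1.0 for the
subject random factor) and the Jeffreys prior on (mu, sigma^2).

In a *complete balanced* design the contrast blocks are mutually orthogonal
and the marginal covariance ``I + sum_b g_b X_b X_b'`` diagonalizes along
the classical ANOVA projections: block b contributes ``m_b`` eigenvalue
copies of ``1 + c_b g_b`` (m_b = block df, c_b = per-column squared norm
N / prod(levels of b)), and the quadratic form needs only the classical
sums of squares.  Conditional on g, the marginal likelihood is therefore
closed-form and O(1) to evaluate; the g's are integrated by seeded
Monte-Carlo over their priors, with a proportional error estimate.

Bayes factors are reported against the subject-only null, plus the direct
full-vs-main-effects comparison.  Because effects are standardized, every
Bayes factor is exactly invariant under rescaling of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import gammaln, logsumexp

from .inference import _score_array, ss_decomposition

__all__ = ["BayesFactorSet", "jzs_model_bfs", "jzs_bayes_factors", "MODEL_NAMES"]

MODEL_NAMES = (
    "trial_type",
    "alcohol",
    "trial_type+alcohol",
    "trial_type+alcohol+interaction",
)


@dataclass
class BayesFactorSet:
    """Bayes factors of the candidate models against the subject-only null."""

    bf_vs_null: dict[str, float]
    error_vs_null: dict[str, float]  # proportional MC error of each BF
    bf_full_vs_main: float
    error_full_vs_main: float
    log_ml: dict[str, float] = field(default_factory=dict)
    n_mc_samples: int = 0
    seed: int = 0


@dataclass
class _Block:
    name: str
    df: int  # eigenvalue multiplicity
    norm: float  # per-column squared norm c_b
    ss: float  # classical sum of squares q_b
    rscale: float


def _design_blocks(
    y: np.ndarray,
    factor_names: list[str],
    rscale_fixed: float,
    rscale_random: float,
) -> tuple[dict[str, _Block], float, int]:
    """Effect blocks, residual SS and N for a subject x factors array."""
    ss = ss_decomposition(y)
    n_total = y.size
    shape = y.shape
    blocks: dict[str, _Block] = {
        "subject": _Block(
            name="subject",
            df=shape[0] - 1,
            norm=n_total / shape[0],
            ss=ss[(0,)],
            rscale=rscale_random,
        )
    }
    factor_axes = tuple(range(1, y.ndim))
    for r in range(1, len(factor_axes) + 1):
        for subset in combinations(factor_axes, r):
            name = ":".join(factor_names[a - 1] for a in subset)
            blocks[name] = _Block(
                name=name,
                df=int(np.prod([shape[a] - 1 for a in subset])),
                norm=n_total / float(np.prod([shape[a] for a in subset])),
                ss=ss[subset],
                rscale=rscale_fixed,
            )
    total_centered = float(np.sum((y - y.mean()) ** 2))
    residual = total_centered - sum(b.ss for b in blocks.values())
    residual = max(residual, 0.0)
    return blocks, residual, n_total


def _log_marginal(
    model_blocks: list[_Block],
    fixed_ss_outside: float,
    residual: float,
    n_total: int,
    n_mc: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Monte-Carlo log marginal likelihood and proportional error.

    ``fixed_ss_outside`` is the SS of effect blocks absent from the model;
    their directions have unit variance and join the residual.
    """
    base = residual + fixed_ss_outside
    half_nm1 = (n_total - 1) / 2.0
    const = gammaln(half_nm1) - half_nm1 * np.log(np.pi) - 0.5 * np.log(n_total)

    logdet = np.zeros(n_mc)
    quad = np.full(n_mc, base)
    for b in model_blocks:
        # g ~ InvGamma(1/2, r^2/2)
        g = 1.0 / rng.gamma(shape=0.5, scale=2.0 / b.rscale**2, size=n_mc)
        lam = 1.0 + b.norm * g
        logdet += b.df * np.log(lam)
        quad += b.ss / lam
    if not np.all(quad > 0):
        raise FloatingPointError(
            "degenerate data: non-positive quadratic form in the marginal "
            f"likelihood (residual={residual}, outside SS={fixed_ss_outside})"
        )
    logp = const - 0.5 * logdet - half_nm1 * np.log(quad)
    log_ml = float(logsumexp(logp) - np.log(n_mc))
    w = np.exp(logp - logp.max())
    prop_err = float(w.std(ddof=1) / (w.mean() * np.sqrt(n_mc)))
    return log_ml, prop_err


def jzs_model_bfs(
    y: np.ndarray,
    factor_names: list[str],
    models: dict[str, list[str]],
    n_mc_samples: int = 10_000,
    seed: int = 0,
    rscale_fixed: float = 0.5,
    rscale_random: float = 1.0,
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Bayes factors vs. the subject-only null for arbitrary model sets.

    ``y`` is a (subjects x levels...) complete balanced array; ``models``
    maps a model name to the list of fixed-effect block names it contains
    (main effects by factor name, interactions as "a:b").  Every model also
    contains the subject block.  Returns (bf_vs_null, combined proportional
    error per BF, log marginal likelihoods including "null", raw per-model
    proportional errors).
    """
    blocks, residual, n_total = _design_blocks(
        y, factor_names, rscale_fixed, rscale_random
    )
    fixed_names = [n for n in blocks if n != "subject"]
    rng = np.random.default_rng(seed)

    log_ml: dict[str, float] = {}
    prop: dict[str, float] = {}
    for name, included in [("null", [])] + list(models.items()):
        unknown = set(included) - set(fixed_names)
        if unknown:
            raise KeyError(f"model {name!r} names unknown effect(s): {unknown}")
        model_blocks = [blocks["subject"]] + [blocks[e] for e in included]
        outside = sum(blocks[e].ss for e in fixed_names if e not in included)
        log_ml[name], prop[name] = _log_marginal(
            model_blocks, outside, residual, n_total, n_mc_samples, rng
        )

    bf = {
        name: float(np.exp(log_ml[name] - log_ml["null"])) for name in models
    }
    err = {
        name: float(np.hypot(prop[name], prop["null"])) for name in models
    }
    return bf, err, log_ml, prop


def jzs_bayes_factors(
    score_table,
    measure: str,
    n_mc_samples: int = 10_000,
    seed: int = 0,
    rscale_fixed: float = 0.5,
    rscale_random: float = 1.0,
) -> BayesFactorSet:
    """JZS model comparison for the 2 x 2 alcohol x trial-type design.

    Compares the four candidate models (each main effect alone, both main
    effects, both plus the interaction) against the subject-only null, and
    the full model directly against the main-effects model.
    """
    y = _score_array(score_table, measure)
    models = {
        "trial_type": ["trial_type"],
        "alcohol": ["alcohol"],
        "trial_type+alcohol": ["alcohol", "trial_type"],
        "trial_type+alcohol+interaction": [
            "alcohol",
            "trial_type",
            "alcohol:trial_type",
        ],
    }
    bf, err, log_ml, prop = jzs_model_bfs(
        y,
        ["alcohol", "trial_type"],
        models,
        n_mc_samples=n_mc_samples,
        seed=seed,
        rscale_fixed=rscale_fixed,
        rscale_random=rscale_random,
    )
    full = "trial_type+alcohol+interaction"
    main = "trial_type+alcohol"
    return BayesFactorSet(
        bf_vs_null=bf,
        error_vs_null=err,
        bf_full_vs_main=float(np.exp(log_ml[full] - log_ml[main])),
        error_full_vs_main=float(np.hypot(prop[full], prop[main])),
        log_ml=log_ml,
        n_mc_samples=n_mc_samples,
        seed=seed,
    )
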