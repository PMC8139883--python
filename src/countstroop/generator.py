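"""Synthetic trial-level Counting Stroop data.

The Counting Stroop task shows one to four identical digits (1-4) per trial;
the participant reports *how many* digits are shown while ignoring the digit
identity (the denotation).  Congruent trials have denotation == count,
incongruent trials do not.  This module generates whole crossover studies
(two counterbalanced sessions per participant, alcohol vs. placebo) with the
statistical structure the downstream analysis assumes: an additive alcohol
effect, a trial-type effect partly delivered through residual scaling (so
interference grows across RT quantiles), a conflict-adaptation (Gratton)
effect, ex-Gaussian residuals, and contamination (errors, misses, lapses).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .config import GeneratorConfig

__all__ = [
    "ParticipantEffects",
    "SequenceConstraintError",
    "generate_trial_sequence",
    "simulate_participant_session",
    "simulate_study",
]

INCONGRUENT = "incongruent"
CONGRUENT = "congruent"
ALCOHOL = "alcohol"
PLACEBO = "placebo"
ALCOHOL_FIRST = "alcohol_first"
PLACEBO_FIRST = "placebo_first"

#: canonical column order of the in-memory trial table
TRIAL_COLUMNS = [
    "participant_id",
    "order_group",
    "session_index",
    "condition",
    "trial_index",
    "trial_type",
    "denotation",
    "count",
    "correct_response",
    "response",
    "rt_ms",
    "is_error",
    "is_miss",
]


class SequenceConstraintError(RuntimeError):
    """Raised when a pseudorandom sequence constraint cannot be satisfied."""


@dataclass
class ParticipantEffects:
    """Per-participant random effects (random intercept only)."""

    intercept_ms: float = 0.0


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@lru_cache(maxsize=32)
def _robust_residual_mean(
    mu: float, sigma: float, tau: float, mad_multiplier: float = 3.32
) -> float:
    """Population mean of the ex-Gaussian residual after the robust filter.

    The downstream analysis drops RTs farther than ``mad_multiplier`` raw
    MADs from the group median, a rule that is equivariant under positive
    scaling, so the multiplicative trial-type component is calibrated
    against this *filtered* residual mean: the configured effect is then
    exactly what the cleaning pipeline recovers, rather than a raw-data
    mean that the filter would shave.
    """
    if tau <= 0:
        return mu  # pure normal residual: symmetric, filter leaves the mean
    dist = stats.exponnorm(tau / sigma, loc=mu, scale=sigma)
    med = dist.ppf(0.5)
    span = 20.0 * (sigma + tau)
    mad = optimize.brentq(
        lambda m: dist.cdf(med + m) - dist.cdf(med - m) - 0.5, 1e-9, span
    )
    lo, hi = med - mad_multiplier * mad, med + mad_multiplier * mad
    prob = dist.cdf(hi) - dist.cdf(lo)
    num, _ = integrate.quad(lambda x: x * dist.pdf(x), lo, hi)
    return num / prob


def _balanced_counts(n: int, rng: np.random.Generator) -> np.ndarray:
    """n stimulus counts drawn from {1,2,3,4}, as equal as possible.

    The remainder (n mod 4) is spread over counts chosen uniformly at
    random without replacement.
    """
    base, extra = divmod(n, 4)
    reps = np.full(4, base, dtype=int)
    if extra:
        reps[rng.choice(4, size=extra, replace=False)] += 1
    return np.repeat(np.arange(1, 5), reps)


def _transition_counts(is_inc: np.ndarray) -> np.ndarray:
    """Counts of the four trial-type transitions (CC, CI, IC, II)."""
    pair = is_inc[:-1].astype(int) * 2 + is_inc[1:].astype(int)
    return np.bincount(pair, minlength=4)


def generate_trial_sequence(
    config: GeneratorConfig,
    seed: int | np.random.Generator | None = None,
    max_attempts: int = 10_000,
) -> pd.DataFrame:
    """Generate one session's pseudorandom trial sequence (no behavior).

    Returns a frame with ``trial_index`` (1-based), ``trial_type``,
    ``denotation``, ``count`` and ``correct_response``.  Each trial type
    occurs exactly ``trials_per_type`` times; within each type the four
    stimulus counts are balanced.  Trial-type order is rejection-sampled
    until every transition (CC, CI, IC, II) occurs at least
    ``floor(trials_per_session / 4) - 5`` times, which keeps the
    sequential (conflict-adaptation) analysis estimable.
    """
    if config.trials_per_type < 2:
        raise SequenceConstraintError("trials_per_type must be at least 2")
    rng = _as_rng(seed)
    n_type = config.trials_per_type
    n_total = config.trials_per_session
    min_transitions = n_total // 4 - 5

    if min_transitions > n_type - 1:
        raise SequenceConstraintError(
            "impossible constraint set: each transition type must occur at "
            f"least {min_transitions} times but same-type transitions are "
            f"bounded by trials_per_type - 1 = {n_type - 1}"
        )

    is_inc = np.zeros(n_total, dtype=bool)
    is_inc[:n_type] = True
    for attempt in range(max_attempts):
        rng.shuffle(is_inc)
        if min_transitions <= 0:
            break
        if _transition_counts(is_inc).min() >= min_transitions:
            break
    else:
        raise SequenceConstraintError(
            "transition balance not satisfied: no shuffle with every "
            f"transition type >= {min_transitions} found in {max_attempts} attempts"
        )

    counts = np.empty(n_total, dtype=int)
    denotation = np.empty(n_total, dtype=int)
    inc_idx = np.flatnonzero(is_inc)
    con_idx = np.flatnonzero(~is_inc)
    for idx in (inc_idx, con_idx):
        vals = _balanced_counts(len(idx), rng)
        rng.shuffle(vals)
        counts[idx] = vals
    # congruent: denotation matches the count; incongruent: any other digit
    denotation[con_idx] = counts[con_idx]
    offsets = rng.integers(1, 4, size=len(inc_idx))
    denotation[inc_idx] = (counts[inc_idx] - 1 + offsets) % 4 + 1

    return pd.DataFrame(
        {
            "trial_index": np.arange(1, n_total + 1),
            "trial_type": np.where(is_inc, INCONGRUENT, CONGRUENT),
            "denotation": denotation,
            "count": counts,
            "correct_response": counts,
        }
    )


def _session_behavior(
    is_inc: np.ndarray,
    correct: np.ndarray,
    intercept_ms: float,
    condition: str,
    session_index: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Vectorized behavior model for one session; returns raw arrays."""
    n = is_inc.size
    is_alc = condition == ALCOHOL

    # additive part of the trial-type effect; the rest enters by scaling
    # the (positive-mean) residual on incongruent trials
    frac = config.trialtype_scale_frac
    delta_tt = config.delta_trialtype_ms
    additive_tt = delta_tt * (1.0 - frac)
    if frac > 0 and delta_tt != 0:
        robust_mean = _robust_residual_mean(
            config.residual_mu_ms, config.residual_sigma_ms, config.residual_tau_ms
        )
        scale_inc = 1.0 + delta_tt * frac / robust_mean
    else:
        scale_inc = 1.0

    base = config.grand_mean_rt_ms + intercept_ms
    if session_index == 2:
        base += config.delta_session_ms
    if is_alc:
        base += config.delta_alcohol_ms

    rt = np.full(n, base)
    rt += np.where(is_inc, additive_tt, 0.0)
    if is_alc:
        rt += np.where(is_inc, config.delta_interaction_ms, 0.0)

    # conflict adaptation: alternations slowed, repetitions sped, +-g/4,
    # which yields interference(after congruent) - interference(after
    # incongruent) = gratton_ms without shifting the marginal trial-type
    # effect away from delta_trialtype_ms
    if config.gratton_ms != 0.0:
        adj = np.zeros(n)
        alternation = is_inc[1:] != is_inc[:-1]
        adj[1:] = np.where(alternation, 1.0, -1.0) * (config.gratton_ms / 4.0)
        rt += adj

    resid = rng.normal(config.residual_mu_ms, config.residual_sigma_ms, n)
    resid += rng.exponential(config.residual_tau_ms, n)
    rt += np.where(is_inc, scale_inc, 1.0) * resid

    is_lapse = rng.random(n) < config.lapse_rate
    rt += np.where(is_lapse, config.lapse_shift_ms, 0.0)

    p_err = np.where(is_inc, config.er_incongruent, config.er_congruent)
    if is_alc:
        p_err = p_err + config.er_alcohol_delta
    err_draw = rng.random(n) < p_err
    miss_draw = rng.random(n) < config.miss_rate
    # responses slower than the deadline are never registered; nonpositive
    # RTs (possible only under extreme configs) are treated the same way
    is_miss = miss_draw | (rt > config.response_window_ms) | (rt <= 0)
    is_error = err_draw | is_miss

    wrong = (correct - 1 + rng.integers(1, 4, size=n)) % 4 + 1
    response = np.where(err_draw, wrong, correct).astype(float)
    response[is_miss] = np.nan
    rt = rt.copy()
    rt[is_miss] = np.nan

    return {
        "response": response,
        "rt_ms": rt,
        "is_error": is_error,
        "is_miss": is_miss,
        "is_lapse": is_lapse,
    }


def simulate_participant_session(
    sequence: pd.DataFrame,
    participant_effects: ParticipantEffects,
    condition: str,
    session_index: int,
    config: GeneratorConfig,
    seed: int | np.random.Generator | None = None,
    participant_id: str = "p001",
    order_group: str | None = None,
) -> pd.DataFrame:
    """Simulate the behavior of one participant in one session.

    ``sequence`` must come from :func:`generate_trial_sequence`; the
    participant's random intercept is supplied via ``participant_effects``.
    """
    if condition not in (ALCOHOL, PLACEBO):
        raise ValueError(f"condition must be '{ALCOHOL}' or '{PLACEBO}', got {condition!r}")
    rng = _as_rng(seed)
    is_inc = (sequence["trial_type"] == INCONGRUENT).to_numpy()
    correct = sequence["correct_response"].to_numpy()
    beh = _session_behavior(
        is_inc, correct, participant_effects.intercept_ms, condition,
        session_index, config, rng,
    )
    if order_group is None:
        first_cond = condition if session_index == 1 else (
            PLACEBO if condition == ALCOHOL else ALCOHOL
        )
        order_group = ALCOHOL_FIRST if first_cond == ALCOHOL else PLACEBO_FIRST
    n = len(sequence)
    out = pd.DataFrame(
        {
            "participant_id": np.repeat(participant_id, n),
            "order_group": np.repeat(order_group, n),
            "session_index": np.full(n, session_index),
            "condition": np.repeat(condition, n),
            "trial_index": sequence["trial_index"].to_numpy(),
            "trial_type": sequence["trial_type"].to_numpy(),
            "denotation": sequence["denotation"].to_numpy(),
            "count": sequence["count"].to_numpy(),
            "correct_response": correct,
            **beh,
        }
    )
    return out


def simulate_study(
    config: GeneratorConfig, seed: int | None = None
) -> pd.DataFrame:
    """Simulate the full crossover study (all participants x 2 sessions).

    Session order (alcohol first vs. placebo first) is counterbalanced:
    exactly ``n_participants // 2`` participants receive alcohol in session
    one.  The result is one tidy trial table; the ``is_lapse`` column tags
    generator-injected attentional lapses (useful as an oracle for testing
    the outlier filter) and is not part of the on-disk trial format.
    """
    if config.n_participants < 2:
        raise ValueError("n_participants must be at least 2")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_participants
    order = np.array([PLACEBO_FIRST] * n, dtype=object)
    order[rng.choice(n, size=n // 2, replace=False)] = ALCOHOL_FIRST

    pieces: list[pd.DataFrame] = []
    for i in range(n):
        pid = f"p{i + 1:03d}"
        effects = ParticipantEffects(intercept_ms=rng.normal(0.0, config.subject_sd_ms))
        first = ALCOHOL if order[i] == ALCOHOL_FIRST else PLACEBO
        second = PLACEBO if first == ALCOHOL else ALCOHOL
        for session_index, condition in ((1, first), (2, second)):
            sequence = generate_trial_sequence(config, rng)
            pieces.append(
                simulate_participant_session(
                    sequence, effects, condition, session_index, config, rng,
                    participant_id=pid, order_group=str(order[i]),
                )
            )
    return pd.concat(pieces, ignore_index=True)
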