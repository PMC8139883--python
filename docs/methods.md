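# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `countstroop`.

## Design and measures

The design is a fully within-subject 2 × 2 crossover: every participant
performs the Counting Stroop task in two sessions (alcohol, placebo;
session order counterbalanced across participants) with 160 trials per
session, 80 incongruent and 80 congruent, each trial a 750 ms fixation
followed by a 1000 ms stimulus with no inter-trial interval. Because there
is no inter-trial interval the response deadline is taken as stimulus +
following fixation = 1750 ms (`response_window_ms`, configurable); the
original task description leaves the deadline unstated.

Per participant × condition × trial type the pipeline computes the mean
correct-trial RT (after outlier removal), the error rate ER over all
trials of the cell (misses count as errors), and the inverse efficiency
score IES = RT / (1 − ER). Interference scores are exact
incongruent − congruent differences per measure.

## Cleaning chain (fixed order)

1. **Error/miss marking.** Absent response ⇒ miss ⇒ error.
2. **RT outliers.** Within participant × session × trial type, a correct
   trial is flagged iff |rt − median| > 3.32 × MAD, with the *unscaled*
   MAD (median absolute deviation from the group median). The 1.4826
   consistency constant is deliberately not applied: the 3.32 criterion
   already folds it into the multiplier (3.32 ≈ 2.24 × 1.4826). Flagged
   trials leave every RT aggregate but keep their place in ER
   denominators. Degenerate groups (MAD = 0, ties at the median) exclude
   nothing, and groups with fewer than 3 correct trials are left
   unfiltered with a logged warning.
3. **Below-chance exclusion.** Per session × trial type, a participant is
   excluded (from both sessions — the ANOVA needs complete cases) when the
   exact binomial survivor probability P(X > n_correct),
   X ~ Binomial(n_trials, 0.25), exceeds 0.01. The exact scan puts the
   smallest surviving accuracy for 80 trials at 36.25 %. Whether the two
   sessions should be pooled first is an open reading; both are supported
   (`below_chance_pool_sessions`), per-session being the default.
4. **Winsorization.** Participant-level scores are winsorized per measure ×
   condition × trial type across participants (and interference scores
   additionally per measure × condition) at mean ± 3 sample (n−1) SDs,
   single pass with the bounds computed from the original vector.
   Re-winsorizing the output is deliberately *not* claimed to be a no-op;
   the contract is the single pass from the original vector. Winsorized
   values feed inference; reliability uses unwinsorized per-half scores
   (winsorization is defined on full-sample scores only).

## Repeated-measures ANOVA and effect size

For a complete balanced fully-within design (one observation per subject ×
cell) the sum of squares of every effect subset is obtained by the Möbius
(inclusion–exclusion) expansion of marginal means; each within effect A is
tested against its subject interaction, F = MS_A / MS_{A×subject}, with
df = (df_A, df_A·(n−1)). Generalized eta-squared uses

η²G(A) = SS_A / (SS_A + SS_subjects + Σ_B SS_{B×subject}),

pooling the subject SS and *all* subject-related error SS in the
denominator — the convention for designs in which every factor is
manipulated. Estimated marginal means equal arithmetic cell means in this
balanced setting. No sphericity correction is applied: the main design has
only 2-level factors (correction vacuous), and the 4-level supplemental
analyses follow the same uncorrected convention. The implementation is
validated against an independent brute-force SS oracle, statsmodels'
`AnovaRM` (F, p) and the paired-t identity F = t² for 2-level factors;
pingouin's `ng2` matches the η²G values.

## Sensitivity power analysis

The paired two-tailed t-test is algebraically equivalent to the 2-level
within-factor F-test, so the minimal detectable effect size is defined via
the noncentral t distribution: the smallest d with
P(|T′_{n−1, d√n}| > t_{1−α/2, n−1}) ≥ power, solved by Brent root-finding
to |Δpower| < 10⁻⁶. At n = 40, α = 0.05 the defaults give d = 0.58 at
power 0.95 (the power level is a package default, exposed as an argument)
and d ≈ 0.45 at power 0.80. The scipy noncentral-t tail routines return
NaN deep in the saturated region; the power function falls back to the
double-precision-exact limit there.

## JZS Bayes factors

The model comparison follows the default-prior ANOVA construction:
y = μ1 + Σ_b X_b θ_b + ε with orthonormal sum-to-zero contrast blocks for
the subject factor and each fixed effect, θ_b ~ N(0, g_b σ² I),
g_b ~ InvGamma(1/2, r_b²/2) (Cauchy on standardized effects; r = 0.5 for
fixed effects, 1.0 for the subject block) and Jeffreys priors on (μ, σ²).
In a complete balanced design the blocks are mutually orthogonal and the
marginal covariance diagonalizes along the classical ANOVA projections, so
conditional on g the marginal likelihood is closed-form in the classical
sums of squares; the g's are then integrated by Monte-Carlo over their
priors (default 10,000 draws, seeded) with a proportional error estimate
reported next to each Bayes factor. All candidate models
({trial_type}, {alcohol}, {both}, {both + interaction}) are compared
against the subject-only null, plus the full model directly against the
main-effects model. Standardization makes every BF exactly scale
invariant. Degenerate inputs (zero total variance) raise rather than
returning a non-finite BF.

Two caveats established during validation: (i) for a two-condition
reduction the ANOVA formulation agrees with the closed-form JZS paired-t
Bayes factor (Cauchy scale 0.5 on the difference-score effect size, via
the √2 contrast mapping) only in the null-to-moderate evidence regime; at
strong effects the two models genuinely diverge (a few percent to ~10 %),
because the t-test conditions on difference scores while the ANOVA model
shares σ² across the subject and treatment subspaces. (ii) the Monte-Carlo
integral is additionally validated against direct quadrature of the
generic matrix-form marginal likelihood, which is formulation-identical at
every effect size.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
the study's scale (n = 40, 2 × 160 trials). For a correct trial,

rt = grand_mean (600 ms) + subject intercept (SD 60 ms)
   + session effect (−15 ms training speed-up in session 2)
   + alcohol effect (17 ms) + interaction (0 ms)
   + additive trial-type share + conflict-adaptation adjustment
   + scale(trial type) × ex-Gaussian residual (μ 0, σ 40, τ 80 ms).

Key choices:

- **Trial-type effect, 49 ms**, split by `trialtype_scale_frac` (0.5):
  half enters additively, half by scaling the residual on incongruent
  trials. Because the robust MAD filter trims the right tail, the scale
  factor is calibrated against the *filtered* residual mean (population
  median ± 3.32 raw MADs truncated mean of the ex-Gaussian, computed by
  quadrature and cached), so that the effect the cleaning pipeline
  recovers equals the configured 49 ms; calibrating against the raw mean
  would leave a ≈ −4.5 ms recovery bias. The multiplicative share makes
  interference grow across RT quantiles, as delta plots of conflict tasks
  show.
- **Alcohol effect, 17 ms**, purely additive (slowing regardless of trial
  type); **no interaction** by default.
- **Conflict adaptation, 20 ms**: alternation trials are slowed and
  repetition trials sped by gratton_ms/4 each, which yields
  interference(after congruent) − interference(after incongruent)
  = gratton_ms while leaving the marginal trial-type effect untouched.
- **Errors**: per-trial probabilities 0.04 (congruent) / 0.06
  (incongruent), +0.004 under alcohol; independent misses at 0.003;
  attentional lapses at rate 0.02 add 900 ms (these are the targets of the
  MAD filter and are tagged in memory for oracle tests). Together these
  produce a realized grand-mean ER ≈ 0.055. Error-trial RTs come from the
  same RT model; they are discarded downstream anyway.
- **Sequences**: stimulus counts are balanced within trial type; trial-type
  order is rejection-sampled (cap 10,000 shuffles) until every transition
  type (CC, CI, IC, II) occurs at least ⌊160/4⌋ − 5 = 35 times, keeping
  the sequential analysis estimable.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: no between-subject variance in error rates or in
the size of the interference effect (so ER split-half reliability is near
zero and RT reliability is higher than typical empirical values, ~0.98 vs
~0.85), no speed–accuracy trade-off coupling, no fatigue/drift within a
session, no condition-order carry-over beyond the additive session effect,
and no pharmacology: "alcohol" is a pure condition label, not an exposure
model.

## Problem sizes used in validation

Parameter-recovery checks average 100 replicate studies (seeded,
~20 s total); the type-I-error calibration of the interaction F-test uses
1000 replicate studies and checks the 5 % ± 2 % band; oracle equivalences
run on small designs (n ∈ {3..8}) where brute force is exact. These sizes
give Monte-Carlo standard errors several times smaller than the tested
tolerances.

## Known limitations

- The RM-ANOVA handles complete balanced fully-within designs only;
  incomplete cases fail loudly rather than being dropped silently.
- The Bayes-factor machinery relies on the balanced-design
  diagonalization; unbalanced data would require the generic matrix form.
- The generator's ex-Gaussian + additive-effects model is a convenient
  approximation, not a process (evidence-accumulation) model.
- Reliability is computed on totals aggregated over trial types by
  default; per-trial-type and interference-score reliability are available
  but less stable.
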