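# Methods

## The training task and its bookkeeping

A session is a sequence of `n_trials` image trials.  Each trial has a
category (drug vs healthy living), an orientation that deterministically
encodes the required swipe (portrait = avoid, landscape = approach, by
default; the mapping is configurable per session), and a congruency flag:
congruent trials pair drug cues with avoidance or healthy cues with
approach.  The intended training ratio (ITR) is the congruent fraction.

Construction choices where the design was open:

- **Congruent count** = round-half-up(ITR × n_trials); the stored ITR is
  the realized ratio, always an exact multiple of 1/n_trials, so
  |realized − requested| ≤ 0.5/n.
- **Category composition** is split 50/50 (drug gets ⌊n/2⌋), with the
  congruent trials allocated proportionally between categories, so both
  drug-approach and healthy-avoid incongruent trials occur.
- **Trial order** is a uniform shuffle under an explicit seed; no
  sequential constraints are imposed.
- The static arm uses 156 trials with 144 congruent (ITR 92.3%); adaptive
  sessions default to the same length.

## Performance and difficulty metrics

The performance index is accuracy divided by the median of log response
times.  Units and transform are pinned down as: RT in milliseconds,
natural log, RTs floored at 10 ms, so the median log is strictly positive
and the quotient is stable; the even-count median averages the two central
order statistics.  Omissions should be coded as incorrect trials by the
caller.  With typical RTs near e^7 ≈ 1.1 s, p_t lives on a scale of
roughly 1/7 per unit accuracy, which is why the virtual participant's
intercept defaults to ≈ 0.10.

The difficulty features of a session are ITR, ITR², and the sample SD
(divisor k−1) of the last k ITRs with k = 3.  The rolling SD is reported
as unavailable — not zero — while fewer than k sessions exist; inside the
online fit it is imputed as 0 for those early rows so every session
contributes to the regression (the retrospective analysis instead excludes
the warm-up entirely; both conventions are implemented and the analysis
entry point uses the exclusion).

## The controller

The per-user model regresses p_t on {1, ITR, ITR², SD_k, t, t²} by OLS
over all completed sessions, refitting after each session from the first
post-warm-up session onward.  A linear ITR term is included alongside the
quadratic (the retrospective analysis uses both; a pure-quadratic form
results if the linear column is collinear).  Rank deficiencies are handled
by pruning columns in the fixed order ITR² → SD_k → ITR; a constant-ITR
history therefore yields a fit with all ITR-dependent weights at zero.

**Difficulty reconstruction and orientation.**  The regression identifies
only composite products (e.g. the ITR² weight is β1α1), so difficulty is
recoverable only up to an affine map — which is all the selection rule
needs, since it compares candidates by ordering.  One global sign is not
identifiable from the composites alone: the ITR-dependent part of
*predicted performance* is difficulty scaled by β1.  The package resolves
it with the model's own premise that difficulty depresses performance
(β1 < 0): raw predicted difficulty is the *negated* ITR-part of predicted
performance, then affinely normalized to [0, 1] over the feasible
congruent-count grid.  Without this negation the loop demonstrably tracks
the mirror image of its target.  When the ITR-dependent weights are all
zero the prediction degenerates to a constant 0.5; combined with the
larger-count tie-break this sends the first post-warm-up selection to the
grid maximum, which doubles as the exploration step that breaks the
constant-ITR deadlock.

**Selection.**  For session t+1 every feasible congruent count c is a
candidate; its rolling SD including the candidate is computed, predicted
difficulties are normalized over the candidate set, and the candidate
minimizing |d̂ − d*(t+1)| wins, ties going to the larger (more congruent,
therapeutically more conservative) count.  Grid search is used instead of
inverting the quadratic: it is robust to non-monotone fits and respects
the integer trial constraint.

**Target curves.**  On standardized time u = (2t−1−T)/(T−1) ∈ [−1, 1] the
four canonical shapes are: inverted-U d_lo + (d_hi−d_lo)(1−u²), its
reflection (U), and the cubic ±(2u³−u) rescaled to [d_lo, d_hi] (N,
inverted-N).  Defaults: inverted-U, T = 28 daily sessions, d_lo = 0.15,
d_hi = 0.85, warm-up ITR 144/156, ITR bounded to [0.5, 1] so training is
never majority-incongruent.  Only the warm-up count (3) and the choice of
inverted-U are externally fixed; amplitude, bounds and horizon are package
defaults surfaced in `ControllerConfig`.

## The virtual participant

Session-level performance follows p_t = b0_i + b1 d_t + b2 t + b3 t² + ε,
with subject intercepts b0_i ~ N(μ0, τ²) and the latent difficulty
d = α0 + α1 ITR² + α2 SD_k evaluated on the ITRs actually delivered.
Defaults: μ0 = 0.10, τ = 0.01, b1 = −0.02, b2 = 0.0015, b3 = −2×10⁻⁵,
σ = 0.005, α0 = 4/3, α1 = −4/3 (difficulty 1 at ITR = 0.5, 0 at ITR = 1),
α2 = 0.5.  These keep p_t in (0, 1/L) across a 28-session program for ITRs
in [0.5, 1] and encode "harder sessions → slightly worse performance" with
a slow learning trend.

The trial-level bridge is this package's construction: response times are
log-normal with log-median L = 7 (≈ 1.1 s) and spread 0.2; the session
accuracy target is A = clamp(p_t·L, 0, 1), split so congruent trials are
`incong_penalty` (default 0.05) more accurate than incongruent ones while
the ITR-weighted mixture stays A.  The summary statistic
accuracy/median-log-RT is then unbiased for p_t up to clamping (measured
round-trip error ≈ 0.1–0.2% over 500 sessions).  A `deterministic_trials`
mode realizes expected correct counts exactly with constant RTs, giving a
low-noise participant for closed-loop tests.  What this generator does
*not* emulate: practice effects inside a session, RT–accuracy trade-offs,
fatigue, dropout, or any cognitive-process structure; passing tests
certify the control and inference machinery, not effects in real patients.

## Trial statistics

- **LOCF / ITT.**  Missing post or follow-up scores are replaced by the
  subject's most recent earlier observation; baseline (the averaged double
  rating) must be present.  Imputation flags are retained.
- **Mixed-design ANOVA.**  The group×time interaction is computed in the
  within-subject stratum by model comparison of cell-mean vs time-mean
  fits of subject-centered scores.  For balanced groups this reduces to
  the textbook split-plot decomposition (verified against an independent
  sums-of-squares oracle and against `pingouin`); because the interaction
  is the highest-order term, this is also its Type III sum of squares
  under unequal group sizes.  Degrees of freedom are the
  sphericity-assumed (G−1)(T−1) and (N−G)(T−1); partial η² =
  SS_int/(SS_int+SS_err).
- **Bootstrap.**  The resampling unit is the subject (whole time series),
  stratified by group, preserving within-subject correlation.  BCa
  intervals use the standard bias constant (proportion of resamples below
  the observed value) and jackknife-over-subjects acceleration.  The
  interaction's p-value uses a group-label permutation null, since
  resampling within groups cannot produce a null reference for a
  between-group term.  Type-I error measured at 500 null cohorts of 60
  subjects, B = 2000: ≈ 4–6% at nominal 5%.
- **Pairwise contrasts.**  Within-group contrasts use the paired Cohen d
  on baseline-minus-later differences (reduction = positive d); between
  groups the pooled-SD d.  Bootstrap two-tailed p-values come from the
  centered-data t-statistic null; Bonferroni adjusts within each family
  (6 within-group, 9 between-group contrasts).  Both BCa and percentile
  CIs are reported for d.  Zero-difference contrasts report d = 0;
  constant nonzero differences are flagged degenerate.
- **Relapse.**  Pearson χ² on the 2×k relapse table without continuity
  correction, df = k−1; under intention-to-treat, participants missing at
  follow-up are counted as relapsed before testing.
- **Retrospective mixed model.**  Random-intercept model of p_t on
  {ITR, ITR², t, t², SD₃}, REML via statsmodels, sessions 1–3 excluded
  (constant warm-up ITRs).  Confidence intervals are Wald-t; the default
  fixed-effect covariance is the subject-level CR1 cluster sandwich with
  G−1 degrees of freedom rather than the model-based one, because the
  trial-level response noise leaves mild heteroscedasticity the
  random-intercept structure does not describe; the robust intervals
  restore ≈ 94–95% empirical coverage (measured over hundreds of
  simulated cohorts) where model-based intervals sat near 92%.
  Conditional R² = (var_fixed + var_random)/(var_fixed + var_random +
  var_residual).  A singular random-effects fit falls back to pooled OLS
  and is flagged.

## Synthetic craving cohorts

Baseline craving on a 0–100 visual-analogue scale in this population has
SD exceeding its mean (≈ 6–9 vs ≈ 9–13), i.e. a right-skewed, zero-heavy
distribution; each arm's margin is therefore a zero-inflated gamma (zero
mass 0.5 by default) with the gamma moments solved from the target
mean/SD — infeasible targets raise an error naming the group.  Timepoints
are coupled by a Gaussian copula with exchangeable correlation ρ = 0.6 (a
surfaced guess: the true 16-week stability of VAS craving is unknown).
Group×time effects are standardized shifts applied before clipping to
[0, 100]; note the zero floor attenuates nominal shifts for zero-heavy
margins, exactly as a floor does in real VAS data.  Defaults: arms of
40/48/48 subjects, follow-up attrition 2/0/3 (hence 131 of 136 follow-up
scores, a 4% dropout rate), zero observed relapses in every arm.

## Problem sizes and numerical choices

Simulation-based checks ship at sizes chosen to balance Monte-Carlo error
against runtime: 500 seeds for the generator/metric round trip, 50 paired
seeds for adaptive-vs-static tracking, 100 cohorts of 50×28 sessions for
slope coverage, 500 null trials at B = 2000 for test calibration (the
analysis default remains B = 10,000).  Collinearity is detected at rank
tolerance 1e-8; normalization spans below 1e-12 degenerate to the constant
0.5; selection ties within 1e-12 go to the larger congruent count.

## Known limitations

- The controller is one consistent realization of curve tracking; the
  original deployed algorithm is proprietary and not reconstructable.
- The raw coefficient scale of the retrospective model depends on the
  (unstated) scaling of the performance index, so only signs and relative
  magnitudes are comparable across implementations; an optional per-cohort
  z-standardization of p_t is provided.
- LOCF is the only imputation offered; no survival modeling of relapse.
- The reading of the performance index as a quotient (accuracy over median
  log RT) follows its verbal description; all downstream scales inherit
  that choice.
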