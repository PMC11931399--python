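# apbm — adaptive approach-bias-modification training

Approach-bias modification (ApBM) is a cognitive-bias-modification training
for substance use disorders: drug cues are paired with avoidance actions
(swipe away) and healthy cues with approach actions, retraining the
automatic tendency to approach drug-related stimuli.  Static ApBM keeps the
task identical for weeks and is notoriously boring; adaptive ApBM (A-ApBM)
instead steers each user's session difficulty along a planned trajectory.

This package implements that adaptive system end to end, together with the
statistics used to evaluate it in a three-arm randomized trial, so that the
whole closed loop can be exercised, tested and calibrated on synthetic
data.  It is aimed at researchers designing adaptive digital interventions
and at statisticians who want a reference implementation of the analysis
pipeline.

## The model

A session at index *t* is an ordered set of trials with an **intended
training ratio** ITR_t — the fraction of *congruent* trials (drug→avoid,
healthy→approach).  The per-session **performance index** is

    p_t = accuracy / median(log RT),

and the latent **difficulty index** is modeled as

    d_t = α0 + α1·ITR_t² + α2·SD(ITR_{t−k+1}, …, ITR_t),      k = 3,

an inverted-U in ITR (a 50% ITR is maximally unpredictable, hence hardest)
plus a volatility term.  Performance and difficulty are linked per user *i*
by

    p_t = β_i0 + β1·d_t + β2·t + β3·t² + ε_t .

The controller runs 3 warm-up sessions at a fixed ITR of 144/156 (92.3%),
then after each session refits, by ordinary least squares on the user's
cumulative data, the composite weights {β1α1, β1α2, …} of performance on
{ITR, ITR², rolling SD, t, t²}.  Because only products of α's and β's are
identifiable, predicted difficulty is reconstructed up to an affine map and
normalized to [0, 1] over the feasible ITR grid; the next session's
congruent count is the grid point whose normalized predicted difficulty is
closest to a predetermined inverted-U target curve.  A virtual-participant
model generates trial-level responses (Bernoulli correctness split by
congruency, log-normal RTs) whose session summaries are unbiased for the
linear model above, closing the loop for simulation.

The trial pipeline covers LOCF intention-to-treat completion, the
mixed-design ANOVA group×time interaction with subject-level bootstrap,
BCa intervals and a permutation p-value, bootstrapped pairwise Cohen *d*,
the k-sample equality-of-proportions χ² for relapse, and the retrospective
random-intercept mixed model of performance on the difficulty features.

## Worked example

Run one simulated trainee through the 28-session adaptive program:

```python
import numpy as np
from apbm import ControllerConfig, ParticipantModel, VirtualParticipant, run_loop

cfg = ControllerConfig(total_sessions=28, schedule_seed=7)
trainee = VirtualParticipant(ParticipantModel(), rng=np.random.default_rng(7))
result = run_loop(trainee, cfg, subject_id="demo")
print(result.trace[["t", "itr_selected", "d_target", "d_predicted", "performance"]]
      .round(3).iloc[[0, 3, 6, 13, 20, 27]].to_string(index=False))
```

```
 t  itr_selected  d_target  d_predicted  performance
 1         0.923     0.150          NaN        0.098
 4         0.923     0.427          NaN        0.107
 7         0.603     0.634        0.205        0.088
14         0.538     0.849        0.867        0.108
21         0.865     0.688        0.575        0.122
28         0.942     0.150        0.155        0.118
```

Sessions 1–4 hold the warm-up ITR of 92.3% while the per-user model has no
information.  As data accumulate the selected ITR moves toward 50% (harder)
into the mid-program difficulty peak (`d_target` 0.849 at t = 14) and back
toward all-congruent (easier) sessions at the end; `d_predicted` is the
controller's normalized difficulty estimate for the chosen ITR, which
tracks the target once the fit stabilizes.

Analyze a synthetic three-arm craving trial (arms of 40/48/48 subjects,
0–100 craving scores at baseline/post/follow-up, attrition 2/0/3):

```python
from apbm import default_craving_spec, generate_craving, locf_impute, bootstrap_interaction
table = locf_impute(generate_craving(default_craving_spec(seed=1)))
res = bootstrap_interaction(table, B=2000, seed=1)
print(f"F({res.df_num}, {res.df_den}) = {res.F:.2f}, "
      f"partial eta^2 = {res.partial_eta_sq:.3f}, "
      f"95% BCa CI for F = ({res.ci_F[0]:.2f}, {res.ci_F[1]:.2f}), "
      f"bootstrap p = {res.p:.2f}")
```

```
F(4, 266) = 1.52, partial eta^2 = 0.022, 95% BCa CI for F = (0.10, 3.74), bootstrap p = 0.19
```

This cohort was generated with no group×time effect, so the interaction is
(correctly) nonsignificant; the degrees of freedom (4, 266) follow from
the 136-subject, 3-group, 3-timepoint design.

A command-line interface mirrors the library:

```sh
apbm fixtures --out fx            # synthetic craving + relapse tables
apbm analyze --craving fx/craving.csv --relapse fx/relapse.csv --out report
apbm control --arm a_apbm --subjects 5 --out traces
apbm simulate --subjects 20 --out cohort
```

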