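# mentakin

Movement kinematics, animations-task scoring, and Bayesian hierarchical
models for a placebo-controlled crossover study of dopamine and mentalising
— exercised end to end on a synthetic cohort with known ground truth.

## The problem

Does disrupting dopamine D2/D3 signalling impair the ability to infer other
agents' mental states?  The study design this package implements answers
that with a within-subject crossover: each participant receives haloperidol
(HAL) on one day and placebo (PLA) on the other (order counterbalanced) and,
on both days, animates and then watches short two-triangle animations
depicting mental-state words (*seducing*, *surprising*) and non-mental words
(*following*, *fighting*), rating each viewed clip on four 1–10 scales.
Accuracy on a trial is

```
accuracy = rating(target word) − mean(ratings of the 3 non-target words)
```

and the drug effect is estimated by Bayesian mixed-effects models such as

```
accuracy ~ drug * mental_state + (1 + drug || subject) + (1 | animation)
```

with normal priors on coefficients, half-Cauchy priors on standard
deviations, posterior means (Eμ), 95% credible intervals and sign
probabilities P(Eμ<0) as the reported quantities, and PSIS-LOO for model
comparison.  Secondary analyses couple the drug effect to movement: *jerk
difference* — |observer's own mean jerk for a word − stimulus mean jerk|,
with jerk the third time-derivative of the recorded triangle positions —
indexes observer–animator movement similarity, and change-score models link
drug effects on animation labelling to drug effects on whole-body emotion
recognition and working memory.

The package is aimed at researchers who want a tested, reusable
implementation of this analysis chain: a synthetic crossover cohort
generator with configurable true effects, the kinematic estimators, the
scoring scheme, a registry of all seventeen study models (Gaussian,
truncated Student-t, and two-component Gaussian-mixture response families),
and a file-based pipeline with a CLI.  See `docs/methods.md` for the full
model and generator description.

## Worked example

Simulate a 33-subject cohort at the designed effect sizes (drug effect
−0.66, mental-state effect −2.50 on the accuracy scale), score it, and fit
the headline models:

```bash
python analysis/01_simulate_cohort.py --seed 1   # raw cohort CSVs
python analysis/02_kinematics.py                 # mean speed/jerk + jerk differences
python analysis/03_score.py                      # accuracy, change scores
python analysis/04_fit_models.py --seed 1        # models 1.1, 1.2, 3.2, 4.2
python analysis/05_mixture_and_loo.py --seed 1   # mixture + LOO comparison
```

`04_fit_models.py` prints (seed 1):

```
Model 1.1 (n=2112, max Rhat 1.014)
  drug effect Eμ = -0.72  CrI [-0.94, -0.51]  P(<0) = 1.00
Model 1.2 (n=2112, max Rhat 1.013)
  drug effect Eμ = -0.53  CrI [-0.81, -0.24]  P(<0) = 1.00
  mental-state effect Eμ = -2.25  CrI [-2.64, -1.86]
Model 3.2 (n=1056, max Rhat 1.016)
  implied placebo jerk-difference slope (mental) = -1.41  CrI [-2.24, -0.59]
Model 4.2 (n=132, max Rhat 1.032)
  implied ER-change slope (mental) = +0.041; ≈ +0.66 extra correct animations per 2 SD
```

Reading: haloperidol lowers labelling accuracy by about 0.7 scale points
with the posterior entirely below zero; mental-state animations are ~2.3
points harder than non-mental ones; on haloperidol days, accuracy for
mental-state animations still tracks similarity to the subject's *placebo*
movements (negative slope); and subjects whose emotion recognition suffered
more under the drug also lost more animation accuracy — a 2 SD difference
in ER change corresponds to roughly two thirds of one extra correctly
labelled animation per word.  All four recoveries match the cohort's
generating parameters (the similarity slope sits on the global z-scale,
~1.3× the generating within-word scale).  `05_mixture_and_loo.py` fits the
two-component mixture to a bimodal cohort (component means +1.7 / +6.2,
split point 4.3) and prefers the drug-by-mental-state model over drug-only
by PSIS-LOO (elpd difference −7.4 ± 4.2, stacking weight 0.91).

The same stages are available as a CLI (`mentakin simulate|kinematics|
score|fit|compare|report|run-all`) driven by a YAML config, and as library
calls (`mentakin.generate_cohort`, `mentakin.fit`, `mentakin.compare`, …).

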