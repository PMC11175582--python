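# Methods

## Scientific setting

`mentakin` implements, end to end, the quantitative machinery of a
double-blind, placebo-controlled crossover study of dopamine's role in
mentalising.  Each subject attends two sessions — 2.5 mg haloperidol (HAL, a
D2/D3 antagonist) on one day and placebo (PLA) on the other, order
counterbalanced — and in each session:

* animates four words (*seducing*, *surprising*, *following*, *fighting*)
  by moving two triangles on a touchscreen, positions recorded at 133
  frames/s for 35 s;
* views and rates 32 animated-triangle stimuli (8 per word) on four 1–10
  scales, one per candidate word;
* completes 48 point-light-walker emotion-recognition trials, a Sternberg
  working-memory task (set sizes 5–9), and timed 10 m walking passes.

*Seducing* and *surprising* are mental-state words (one triangle acts on the
other's mental state); *following* and *fighting* are non-mental
(goal-directed).  The package provides the kinematic summaries, the scoring
scheme, a registry of seventeen Bayesian hierarchical models over three
analysis tables, PSIS-LOO model comparison, and a synthetic cohort generator
with known ground truth so that the whole chain is testable without any
external data.

## Kinematics

Mean speed is the average Euclidean norm of the first time-derivative of
position, pooled over frames and both triangles; mean jerk is the same for
the third derivative.  Derivatives use central finite differences on the raw
uniformly-sampled positions — a five-point fourth-order stencil for
velocity and the standard five-point second-order stencil for the third
derivative — with no smoothing, evaluated on interior frames only (two
boundary frames dropped per side).  On polynomials up to degree three the
jerk estimator is exact to rounding; on a 1 Hz sinusoid sampled at 133 Hz
the relative stencil error is below 6 × 10⁻⁴ for jerk and 10⁻⁶ for speed.
Timestamps may jitter up to 1% of the mean interval; beyond that the
sampling is rejected rather than silently interpolated.

The observer–animator similarity index ("jerk difference") for a viewed
trial is |own mean jerk for that word − stimulus mean jerk|.  Three variants
are linked to every trial: same-session (own jerk from the trial's session),
placebo-based (own placebo-session jerk, identical to same-session on
placebo trials), and haloperidol-based.  Own jerk pools the two triangles
the subject animated, mirroring the two-agent average used for stimuli.
Walking speed is the mean over passes of pass length (10 m) divided by pass
time.

## Scoring

Trial accuracy = target-word rating − mean of the three non-target ratings,
bounded in [−9, 9].  A trial is *correct* when the target rating strictly
exceeds every non-target rating; a tie counts as incorrect (deterministic
and conservative — the strict reading of "highest rating given to the
target").  Percentage accuracy is the fraction correct of the 8 trials of
one word in one session, so it lives on the lattice {0, 1/8, …, 1}; change
scores are HAL − PLA per subject (and per word for the animations task),
bounded in [−1, 1].  Continuous predictors are z-scored (sample SD) over the
analysis table of the model at hand, after any session subset is applied,
so that coefficients are per-SD effects; statements about "2 SD" changes
multiply a slope by 2.

## Model registry

Seventeen models over three tables, all with treatment-dummy coding
(reference levels: PLA, non-mental, day 1):

| models | response | structure |
| --- | --- | --- |
| 1.1–1.4, 2.1, 3.1 | Gaussian | trial accuracy ~ drug (× mental state × jerk-difference variant / × drug day / × arousal) + uncorrelated subject intercept and drug slope + animation intercept |
| 2.2, 2.3, 3.2 | Gaussian | single-session subsets with subject and animation intercepts |
| 4.1, 4.2 | truncated Student-t on [−1, 1] | accuracy change ~ ER change × mental state (+ WM change × mental state), fixed effects only |
| 5, 6.1–6.3 | mixture of 2 Gaussians | trial accuracy ~ drug (× mental state / × baseline WM) + subject intercept |
| 7.1, 7.2 | Gaussian | walking speed ~ drug × baseline WM + subject intercept |

Arousal (1–10 tiredness) enters as an ordered factor with orthogonal
polynomial contrasts up to degree 7, capped at one less than the number of
observed levels.  Models 6.2/6.3 and 7.2 are fitted to median-split
baseline-WM subsets.

## Priors and posterior computation

Priors are zero-centred throughout: normal(0, 2.5) on the intercept and all
regression coefficients, half-Cauchy(0, 2.5) on every standard deviation
(residual, random-effect, mixture-component).  The exact scales are a
package choice in the generic-weakly-informative family.  The mixture gap
carries a half-normal(0, 5) prior and the mixing weight a uniform prior;
the Student-t degrees of freedom get gamma(2, 0.1).  Credible intervals are
equal-tailed percentiles (2.5/97.5), not HPD.

No gradient-based probabilistic-programming backend is used; posterior
sampling is the affine-invariant stretch-move ensemble (emcee) with a
deterministic seeded state.  Two family-specific strategies keep this
robust:

* **Gaussian mixed models** are sampled on their *marginal* likelihood:
  with u = (fixed effects, random effects), prior u ~ N(0, D) and
  y | u ~ N(Wu, σ²I), the marginal y ~ N(0, σ²I + WDWᵀ) is evaluated
  through the (p+q)-dimensional precision D⁻¹ + WᵀW/σ² (one small Cholesky
  per evaluation), so the ensemble only explores the 2–4 log-scale variance
  parameters and cannot encounter funnel geometry.  Coefficient and
  random-effect draws are then recovered *exactly* from their conditional
  Gaussian given each variance draw — these conditional draws are
  independent across iterations, which is why fixed-effect Rhat values sit
  at 1.00.
* **Truncated-t and mixture families** are sampled directly (coefficients,
  scales, shape/weight parameters, non-centred random intercepts); the
  mixture is identified by parameterising the upper component mean as the
  lower mean plus a strictly positive gap.

Walkers are initialised in a small ball around a least-squares centre and
partitioned into 4 groups that play the role of chains for split-Rhat
(computed with arviz).  The default budget mirrors a 4-chain, 5,000
iteration, 1,000-warmup run; tests and the acceptance script use reduced
budgets (typically 900–1,500 ensemble steps with thinning), which the
marginalised Gaussian scheme tolerates because its hard dimensions number
at most four.  The convergence gate is max Rhat ≤ 1.01; ensemble moves have
no divergences, so the divergence count is identically zero and the Rhat
gate carries the diagnostic load.  Ensemble steps are serially correlated,
so reported effective sample sizes are smaller than draw counts; thinning
(3–5) keeps this mild.

Pointwise log-likelihoods are stored per posterior draw (conditional on the
random effects for the Gaussian family) and fed to arviz's PSIS-LOO;
comparisons report elpd, elpd differences relative to the best model
(negative below it), their standard errors, and stacking weights.  Fits may
only be compared when fitted to the identical observation set, enforced by
an observation-index check.

Sign probabilities P(Eμ<0)/P(Eμ>0) are empirical CDF values of the draws at
zero; with continuous samplers they sum to one.  "Implied" slopes in the
mental-state condition are summaries of the draw-wise sum of the base slope
and its interaction contrast.

## Synthetic cohort generator

The generator is the package's definition of the study conditions, with
ground truth held in `GeneratorParams`.  Defaults are the magnitudes the
analysis is designed to detect: grand mean accuracy 3.0 (non-mental,
placebo), drug effect −0.66, mental-state effect −2.50, jerk-similarity
slopes −0.11 (non-mental) and −0.54 (mental contrast), subject intercept SD
1.0, subject drug-slope SD 0.5, animation intercept SD 0.6, residual SD
2.2, all on the accuracy scale.  The two-component structure
(`mixture_weight`, default 0 = unimodal; `mixture_separation` 4.5) shifts a
random subset of trials upward, reproducing the bimodal accuracy histograms
that motivate the mixture models.

Three deliberate design choices:

* **Trajectories are band-limited harmonic paths**, not splines through
  waypoints: sums of three sinusoids around a dominant angular frequency
  ω₀ = √(jerk/speed) (for a sinusoid, jerk/speed = ω²).  Amplitude scaling
  and time scaling act exactly and oppositely on speed (a·ω) and jerk
  (a·ω³), so the realised mean speed hits its target to well within ±10%
  while positions stay on the canvas.  Each word occupies its own
  speed/frequency band (*fighting* fast and jerky, *seducing* slow and
  smooth), and sessions select 8 stimuli per word stratified across the
  pool's speed quantiles, so viewed stimuli span each word's full speed
  distribution.
* **Accuracy is driven by the *placebo* jerk difference** — the similarity
  of a stimulus to the observer's stable motor repertoire — while
  haloperidol scales the subject's own movement frequency up (×1.35) and
  speed down (×0.92).  Same-session similarity models therefore lose their
  mental-state similarity effect under haloperidol while placebo-based
  models retain it, which is exactly the contrast the 2.x vs 3.x model
  pairs are built to detect.  The similarity slopes act on the placebo jerk
  difference *centred within word* and scaled by one pooled SD: an
  uncentred predictor would be collinear with the mental-state category
  (words occupy different kinematic bands) and the named drug and
  mental-state parameters would stop being marginal effects, while the
  single pooled scale keeps the per-unit slope uniform across words.  The
  analysis models z-score the raw predictor globally, as the study
  convention dictates, so fitted similarity slopes sit on a modestly larger
  scale (raw SD / within-word SD ≈ 1.3 at the defaults) than the generating
  value; credible intervals cover the rescaled truth.
* **Ratings encode the latent accuracy exactly**: target scale = 5.5 +
  accuracy/2, non-targets = 5.5 − accuracy/2 plus zero-sum jitter shrunk to
  the scale bounds (and to the residual SD, so a noise-free configuration
  gives four equal ratings).  The scoring formula then returns the clipped
  latent accuracy to rounding.

Auxiliary streams: emotion stimuli keep the canonical speed ordering sad <
happy < angry; each subject carries an emotion-recognition drug effect
(mean −0.3, SD 0.5 on the ER accuracy scale) whose cohort z-score shifts
the subject's haloperidol effect on *mental-state* animation trials by
`er_coupling_slope` (0.4) accuracy points per SD — the generative source of
the ER-coupling finding.  Working memory is Bernoulli around the subject's
baseline with a 0.04/item set-size cost; walking speed is 1.25 m/s with a
drug effect moderated by baseline WM (−0.05 + 0.06 per WM SD under
haloperidol), realised as noisy 10 m pass times over a 120 s walk.

What the generator does **not** emulate: attrition, session-order learning
effects, rating response times, realistic human motor noise, or any real
video content.  Passing tests therefore demonstrate that the pipeline
recovers known effects under its own stated noise model, not that the
effects exist in human data.

## Problem sizes and numerics

Tests and the acceptance script simulate trajectories at 2–3 s and 50
frames/s rather than 35 s and 133 frames/s: mean speed and jerk are
stationary summaries, so the resolution affects only run time, and the
frame-count design checks use the full-resolution generator directly.
Cohorts of 10–33 subjects are used depending on the check; credible-interval
calibration uses 25 replicate fits and sign recovery 25 replicate cohorts.
Degenerate inputs fail loudly: constant predictors, missing columns, trials
without a matching self-animation, non-uniform sampling, fewer than four
frames, unknown model names, and comparisons across different observation
sets each raise a dedicated error.

## Known limitations

* The ensemble sampler's chains are walker groups, not independent chains;
  Rhat is interpreted accordingly and backed by the exactness of the
  conditional coefficient draws in the Gaussian family.
* The mixture family supports a single random-intercept block and shared
  slopes across components (component-specific intercepts and scales); the
  registry models need no more.
* The truncated-t family is fixed-effects only, matching the change-score
  models, which found no subject-level variance to explain.
* The emotion-recognition accuracy formula reuses the target-minus-mean-
  non-target scheme over the three emotion scales; the original task's
  exact formula lives in prior work and may differ in detail.
* Printed posterior estimates from the human cohort are not reproducible
  here by construction — the synthetic cohort shares the design and effect
  magnitudes, not the data.
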