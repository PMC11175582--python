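"""Synthetic crossover cohort with known ground truth.

Emulates a double-blind, placebo-controlled within-subject haloperidol (HAL)
vs placebo (PLA) study: each subject attends two sessions in counterbalanced
order and, per session, animates four words with two triangles, views and
rates 32 animated-triangle stimuli (8 per word, four 1–10 scales), completes
48 point-light-walker emotion-recognition trials and a letter-string working
memory task, and walks timed 10 m passes.

The generative model for trial-level animation accuracy mirrors the
hierarchical structure of the analysis models: a grand mean, a drug effect, a
mental-state effect, jerk-similarity slopes (split into a non-mental slope
and a mental-state contrast), subject random intercepts and drug slopes,
animation random intercepts, Gaussian residual noise, and an optional
two-component structure that shifts a random subset of trials upwards by a
separation constant (bimodal accuracy).  Crucially, the similarity predictor
that truly drives accuracy is the *placebo* jerk difference — the observer's
stable motor repertoire — while haloperidol perturbs the kinematics of the
observer's same-day animations.  Same-session and placebo-based similarity
models therefore behave differently downstream, as they should.

Trajectories are band-limited harmonic paths: sums of a few sinusoids whose
amplitude and time scales are adjusted analytically so the realised mean
speed hits its target exactly (speed scales as amplitude x frequency, jerk
as amplitude x frequency cubed), keeping every position on the canvas.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import kinematics as kin
from .errors import InvalidDesignError, ParameterError
from .scoring import WORDS, mental_state_of, standardise

CANVAS = (1280.0, 1024.0)
TRIALS_PER_WORD = 8
EMOTION_TRIALS = 48
EMOTIONS = ("angry", "happy", "sad")
#: Mean stimulus speed per emotion (sad slowest, angry fastest).
EMOTION_SPEED = {"sad": 0.70, "happy": 1.00, "angry": 1.40}
WM_SET_SIZES = (5, 6, 7, 8, 9)
WM_TRIALS_PER_SET = 6

#: Per-word mean-speed band (canvas units/s) and dominant angular-frequency
#: band (rad/s); fighting is fast and jerky, seducing slow and smooth.
WORD_SPEED_BAND = {
    "seducing": (50.0, 100.0),
    "surprising": (90.0, 160.0),
    "following": (60.0, 110.0),
    "fighting": (130.0, 220.0),
}
WORD_OMEGA_BAND = {
    "seducing": (5.0, 8.0),
    "surprising": (8.0, 12.0),
    "following": (6.0, 9.0),
    "fighting": (10.0, 15.0),
}
POOL_PER_WORD = 16


@dataclass(frozen=True)
class GeneratorParams:
    """Ground-truth parameters of the synthetic cohort.

    Accuracy-model effects are on the trial accuracy scale (−9..9); the
    drug and mental-state defaults are the magnitudes the analysis models
    are designed to detect.  Jerk slopes apply to the z-scored placebo jerk
    difference.  ``er_coupling_slope`` shifts a subject's drug effect on
    *mental-state* trials by that many accuracy points per SD of their
    emotion-recognition change.  Walking parameters are in m/s;
    ``walk_wm_interaction`` is per SD of baseline working memory.
    """

    grand_mean_accuracy: float = 3.0
    drug_effect: float = -0.66
    mental_state_effect: float = -2.50
    jerk_diff_slope_nonmental: float = -0.11
    jerk_diff_slope_mental_contrast: float = -0.54
    er_coupling_slope: float = 0.40
    subject_sd: float = 1.0
    subject_drug_slope_sd: float = 0.5
    animation_sd: float = 0.6
    residual_sd: float = 2.2
    mixture_weight: float = 0.0
    mixture_separation: float = 4.5
    walk_drug_effect: float = -0.05
    walk_wm_interaction: float = 0.06
    seed: int = 0
    # Motor-level drug action on self-produced animations: haloperidol makes
    # one's own movements slower and jerkier, decorrelating same-day jerk
    # difference from the placebo-day value.
    self_jerk_drug_scale: float = 1.35
    self_speed_drug_scale: float = 0.92
    # Auxiliary-stream settings (ER accuracy scale −9..9; WM proportion).
    er_base: float = 3.5
    er_subject_sd: float = 0.8
    er_drug_effect_mean: float = -0.30
    er_drug_effect_sd: float = 0.50
    er_residual_sd: float = 1.5
    wm_drug_effect_sd: float = 0.04
    walk_base_speed: float = 1.25
    walk_subject_sd: float = 0.12
    walk_pass_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        sds = {
            "subject_sd": self.subject_sd,
            "subject_drug_slope_sd": self.subject_drug_slope_sd,
            "animation_sd": self.animation_sd,
            "residual_sd": self.residual_sd,
            "er_subject_sd": self.er_subject_sd,
            "er_drug_effect_sd": self.er_drug_effect_sd,
            "er_residual_sd": self.er_residual_sd,
            "walk_subject_sd": self.walk_subject_sd,
            "walk_pass_noise_sd": self.walk_pass_noise_sd,
        }
        for name, v in sds.items():
            if v <= 0:
                raise ParameterError(f"{name} must be strictly positive, got {v}")
        if not (0.0 <= self.mixture_weight <= 1.0):
            raise ParameterError("mixture_weight must lie in [0, 1]")

    def replace(self, **kw) -> "GeneratorParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class SubjectPlan:
    subject_id: str
    drug_order: tuple  # e.g. ("HAL", "PLA"): treatment on day 1, day 2
    baseline_wm: float
    arousal_by_session: tuple  # (day 1, day 2), integers 1..10

    def __post_init__(self) -> None:
        if sorted(self.drug_order) != ["HAL", "PLA"]:
            raise InvalidDesignError("drug_order must contain HAL and PLA once each")
        for a in self.arousal_by_session:
            if not (1 <= int(a) <= 10 and int(a) == a):
                raise InvalidDesignError("arousal must be an integer in [1, 10]")


@dataclass(frozen=True)
class CohortDesign:
    n_subjects: int
    subjects: tuple
    seed: int

    def treatment_on_day(self, subject: SubjectPlan, day_index: int) -> str:
        return subject.drug_order[day_index - 1]


def generate_design(n_subjects: int, seed: int) -> CohortDesign:
    """Counterbalanced two-session crossover design.

    Alternates HAL-first / PLA-first across subjects so the order split is
    exact for even cohorts and off by one otherwise.  Baseline working
    memory (proportion correct) and per-session arousal (1–10 tiredness,
    slightly raised on drug days) are subject traits drawn here.
    """
    if n_subjects < 2:
        raise InvalidDesignError("a crossover cohort needs at least 2 subjects")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    subjects = []
    for i in range(n_subjects):
        order = ("HAL", "PLA") if i % 2 == 0 else ("PLA", "HAL")
        wm = float(np.clip(rng.normal(0.80, 0.08), 0.55, 0.97))
        arousal = []
        for day in (1, 2):
            is_hal = order[day - 1] == "HAL"
            a = rng.normal(4.0, 2.0) + (0.7 if is_hal else 0.0)
            arousal.append(int(np.clip(round(a), 1, 10)))
        subjects.append(
            SubjectPlan(
                subject_id=f"S{i + 1:02d}",
                drug_order=order,
                baseline_wm=wm,
                arousal_by_session=tuple(arousal),
            )
        )
    return CohortDesign(n_subjects=n_subjects, subjects=tuple(subjects), seed=seed)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

_HARMONICS = np.array([0.5, 1.0, 1.9])
_WEIGHTS = np.array([0.35, 1.0, 0.12])


def generate_trajectory(
    word: str,
    kinematic_target: tuple,
    duration_s: float = 35.0,
    rate_hz: float = 133.0,
    seed: int = 0,
    animation_id: str | None = None,
) -> kin.Trajectory:
    """Two-agent harmonic path hitting a target mean speed.

    ``kinematic_target`` is (mean_speed, mean_jerk) in canvas units; the
    dominant angular frequency is set to sqrt(jerk/speed) (for a sinusoid,
    jerk/speed = omega^2) and amplitudes are scaled so the realised mean
    speed matches the target; if the required amplitude would leave the
    canvas the path is shrunk in space and sped up in time, which preserves
    mean speed exactly.
    """
    speed_t, jerk_t = float(kinematic_target[0]), float(kinematic_target[1])
    if speed_t <= 0 or jerk_t <= 0:
        raise ParameterError("kinematic targets must be strictly positive")
    if duration_s <= 0 or rate_hz <= 0:
        raise ParameterError("duration and rate must be strictly positive")
    omega0 = np.sqrt(jerk_t / speed_t)
    n = int(np.floor(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    rng = np.random.default_rng(seed)
    centres = np.array(
        [[0.35 * CANVAS[0], 0.5 * CANVAS[1]], [0.65 * CANVAS[0], 0.5 * CANVAS[1]]]
    )

    def agent_path(centre: np.ndarray, time_scale: float, amp: float) -> np.ndarray:
        xy = np.empty((n, 2))
        for c in range(2):
            w = _WEIGHTS * (1.0 + rng.uniform(-0.2, 0.2, _HARMONICS.size))
            phases = rng.uniform(0, 2 * np.pi, _HARMONICS.size)
            om = omega0 * _HARMONICS * time_scale
            xy[:, c] = centre[c] + amp * np.sum(
                w[None, :] * np.sin(om[None, :] * t[:, None] + phases[None, :]),
                axis=1,
            )
        return xy

    # First pass with unit amplitude fixes the waveform; the random state is
    # then rewound so the scaled pass regenerates the identical waveform.
    state = rng.bit_generator.state
    unit = np.stack([agent_path(centres[a], 1.0, 1.0) for a in range(2)])
    traj = kin.Trajectory("unit", word, t, unit, rate_hz)
    s0 = kin.compute_mean_speed(traj)
    amp = speed_t / s0
    # Largest excursion the canvas allows from either centre.
    headroom = min(
        0.33 * CANVAS[0], 0.5 * CANVAS[1] - 10.0
    )
    dev = float(np.max(np.abs(unit - centres[:, None, :]))) * amp
    shrink = min(1.0, headroom / dev)
    rng.bit_generator.state = state
    xy = np.stack(
        [agent_path(centres[a], 1.0 / shrink, amp * shrink) for a in range(2)]
    )
    return kin.Trajectory(
        animation_id or f"{word}_traj", word, t, xy, rate_hz
    )


def _stimulus_pool(
    seed_seq: np.random.SeedSequence, duration_s: float, rate_hz: float
) -> tuple:
    """Per-word stimulus pools spanning each word's speed band.

    Speeds sit at the quantile midpoints of the band (with a little jitter)
    so that stratified selection of 8 stimuli covers the full speed
    frequency distribution of the pool.
    """
    rng = np.random.default_rng(seed_seq)
    trajectories: dict[str, kin.Trajectory] = {}
    rows = []
    for word in WORDS:
        lo, hi = WORD_SPEED_BAND[word]
        olo, ohi = WORD_OMEGA_BAND[word]
        for i in range(POOL_PER_WORD):
            q = (i + 0.5) / POOL_PER_WORD
            speed = lo + q * (hi - lo) * (1.0 + rng.uniform(-0.03, 0.03))
            omega = rng.uniform(olo, ohi)
            jerk = speed * omega**2
            anim_id = f"stim_{word}_{i:02d}"
            tr = generate_trajectory(
                word,
                (speed, jerk),
                duration_s,
                rate_hz,
                seed=int(rng.integers(2**31)),
                animation_id=anim_id,
            )
            trajectories[anim_id] = tr
            summ = kin.summarise(tr)
            rows.append(
                {
                    "animation_id": anim_id,
                    "word": word,
                    "mean_speed": summ.mean_speed,
                    "mean_jerk": summ.mean_jerk,
                }
            )
    return trajectories, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ratings
# ---------------------------------------------------------------------------

def latent_accuracy(
    trial_context: Mapping,
    truth: GeneratorParams,
    latent_effects: Mapping,
    rng: np.random.Generator,
) -> float:
    """Draw a latent trial accuracy from the generative linear predictor."""
    is_hal = 1.0 if trial_context["treatment"] == "HAL" else 0.0
    is_mental = 1.0 if trial_context["mental_state"] == "mental" else 0.0
    jd_z = float(trial_context.get("jerk_diff_z", 0.0))
    eta = (
        truth.grand_mean_accuracy
        + truth.drug_effect * is_hal
        + truth.mental_state_effect * is_mental
        + (
            truth.jerk_diff_slope_nonmental
            + truth.jerk_diff_slope_mental_contrast * is_mental
        )
        * jd_z
        + float(latent_effects.get("subject_intercept", 0.0))
        + float(latent_effects.get("subject_drug_slope", 0.0)) * is_hal
        + float(latent_effects.get("animation_intercept", 0.0))
        + truth.er_coupling_slope
        * float(latent_effects.get("er_change_z", 0.0))
        * is_hal
        * is_mental
    )
    if truth.mixture_weight > 0 and rng.random() < truth.mixture_weight:
        eta += truth.mixture_separation
    return eta + rng.normal(0.0, truth.residual_sd)


def ratings_from_accuracy(
    accuracy: float,
    target_word: str,
    rng: np.random.Generator,
    jitter_scale: float = 0.4,
) -> dict:
    """Map a latent accuracy onto four bounded 1–10 scales.

    Target scale sits at midpoint + accuracy/2, non-targets at midpoint −
    accuracy/2 plus zero-sum jitter shrunk to respect the scale bounds, so
    target − mean(non-targets) equals the (clipped) latent accuracy exactly.
    """
    a = float(np.clip(accuracy, -9.0, 9.0))
    target = 5.5 + a / 2.0
    base = 5.5 - a / 2.0
    jitter = rng.uniform(-1.0, 1.0, 3) * jitter_scale
    jitter -= jitter.mean()
    headroom = min(base - 1.0, 10.0 - base)
    peak = float(np.max(np.abs(jitter)))
    if peak > 0 and peak > headroom:
        jitter *= headroom / peak
    out = {}
    k = 0
    for w in WORDS:
        if w == target_word:
            out[w] = float(target)
        else:
            out[w] = float(base + jitter[k])
            k += 1
    return out


def generate_ratings(
    trial_context: Mapping,
    truth: GeneratorParams,
    latent_effects: Mapping,
    seed: int,
) -> dict:
    """One trial's four scale values (dict word -> rating in [1, 10])."""
    rng = np.random.default_rng(seed)
    a = latent_accuracy(trial_context, truth, latent_effects, rng)
    # Non-target jitter is a noise feature: it shrinks with the residual SD
    # so a noise-free configuration yields exactly equal scales.
    scale = min(0.4, truth.residual_sd)
    return ratings_from_accuracy(a, trial_context["target_word"], rng, scale)


# ---------------------------------------------------------------------------
# Auxiliary streams
# ---------------------------------------------------------------------------

def generate_auxiliary(
    subject: SubjectPlan,
    treatment: str,
    truth: GeneratorParams,
    latent_effects: Mapping,
    rng: np.random.Generator,
) -> tuple:
    """(emotion_trials, wm_trials, walk) for one session.

    Emotion stimuli keep the canonical speed ordering sad < happy < angry;
    the subject's ER drug effect (supplied through ``latent_effects``) shifts
    haloperidol-session ER accuracy.  WM is Bernoulli around baseline_wm with
    a small set-size cost and a subject-level drug effect.  Walking speed
    includes a drug effect moderated by baseline WM, realised as timed 10 m
    pass times over a 120 s walk.
    """
    is_hal = 1.0 if treatment == "HAL" else 0.0
    # Emotion recognition: 16 trials per emotion, 3 rating scales.
    er_rows = []
    er_mu = (
        truth.er_base
        + float(latent_effects.get("er_subject", 0.0))
        + float(latent_effects.get("er_drug_effect", 0.0)) * is_hal
    )
    for i in range(EMOTION_TRIALS):
        emotion = EMOTIONS[i % 3]
        speed = rng.normal(EMOTION_SPEED[emotion], 0.05 if emotion != "angry" else 0.07)
        acc = np.clip(er_mu + rng.normal(0.0, truth.er_residual_sd), -9.0, 9.0)
        target = 5.5 + acc / 2.0
        base = 5.5 - acc / 2.0
        j = rng.uniform(-1.0, 1.0) * 0.4
        j = min(max(j, 1.0 - base), 10.0 - base)
        ratings = {}
        others = [e for e in EMOTIONS if e != emotion]
        ratings[emotion] = float(target)
        ratings[others[0]] = float(base + j)
        ratings[others[1]] = float(base - j)
        er_rows.append(
            {
                "subject_id": subject.subject_id,
                "treatment": treatment,
                "trial": i,
                "emotion": emotion,
                "stimulus_speed": float(speed),
                **{f"rating_{e}": ratings[e] for e in EMOTIONS},
                "er_accuracy": float(
                    ratings[emotion] - 0.5 * (ratings[others[0]] + ratings[others[1]])
                ),
            }
        )
    # Working memory: set sizes 5..9.
    wm_rows = []
    wm_drug = float(latent_effects.get("wm_drug_effect", 0.0))
    for set_size in WM_SET_SIZES:
        p = float(
            np.clip(
                subject.baseline_wm + wm_drug * is_hal - 0.04 * (set_size - 7),
                0.05,
                0.99,
            )
        )
        for j in range(WM_TRIALS_PER_SET):
            wm_rows.append(
                {
                    "subject_id": subject.subject_id,
                    "treatment": treatment,
                    "set_size": set_size,
                    "correct": bool(rng.random() < p),
                }
            )
    # Walking: true speed with drug x baseline-WM moderation.
    wm_z = (subject.baseline_wm - 0.80) / 0.08
    v = (
        truth.walk_base_speed
        + float(latent_effects.get("walk_subject", 0.0))
        + (truth.walk_drug_effect + truth.walk_wm_interaction * wm_z) * is_hal
    )
    v = max(v, 0.3)
    n_passes = max(int(round(120.0 * v / 10.0)), 3)
    times = 10.0 / v + rng.normal(0.0, truth.walk_pass_noise_sd, n_passes)
    times = np.clip(times, 0.5 * 10.0 / v, None)
    walk = kin.WalkRecord(
        subject_id=subject.subject_id,
        treatment=treatment,
        pass_times=tuple(float(x) for x in times),
    )
    return pd.DataFrame(er_rows), pd.DataFrame(wm_rows), walk


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """All generated streams of one synthetic crossover cohort."""

    design: CohortDesign
    params: GeneratorParams
    subjects: pd.DataFrame
    sessions: pd.DataFrame
    animation_trials: pd.DataFrame
    emotion_trials: pd.DataFrame
    wm_trials: pd.DataFrame
    walk: pd.DataFrame
    trajectories: dict
    stimulus_kinematics: pd.DataFrame

    def trajectories_frame(self) -> pd.DataFrame:
        return pd.concat(
            [tr.to_frame() for tr in self.trajectories.values()], ignore_index=True
        )


def generate_cohort(
    n_subjects: int,
    params: GeneratorParams | None = None,
    seed: int | None = None,
    duration_s: float = 35.0,
    rate_hz: float = 133.0,
) -> Cohort:
    """Generate the full five-stream cohort; deterministic given the seed."""
    params = params or GeneratorParams()
    seed = params.seed if seed is None else int(seed)
    design = generate_design(n_subjects, seed)
    ss = np.random.SeedSequence([seed, 202])
    rng_pool, rng_self, rng_trial, rng_aux = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    trajectories, stim_kin = _stimulus_pool(ss.spawn(1)[0], duration_s, rate_hz)
    stim_by_word = {
        w: stim_kin[stim_kin["word"] == w].sort_values("mean_speed").reset_index(drop=True)
        for w in WORDS
    }
    anim_intercepts = {
        aid: rng_pool.normal(0.0, params.animation_sd)
        for aid in stim_kin["animation_id"]
    }

    # Subject latent effects.
    subj_fx = {}
    for plan in design.subjects:
        subj_fx[plan.subject_id] = {
            "subject_intercept": rng_trial.normal(0.0, params.subject_sd),
            "subject_drug_slope": rng_trial.normal(0.0, params.subject_drug_slope_sd),
            "er_subject": rng_aux.normal(0.0, params.er_subject_sd),
            "er_drug_effect": rng_aux.normal(
                params.er_drug_effect_mean, params.er_drug_effect_sd
            ),
            "wm_drug_effect": rng_aux.normal(0.0, params.wm_drug_effect_sd),
            "walk_subject": rng_aux.normal(0.0, params.walk_subject_sd),
            "speed_factor": float(np.exp(rng_self.normal(0.0, 0.15))),
            "omega_factor": float(np.exp(rng_self.normal(0.0, 0.15))),
        }
    er_fx = np.array([subj_fx[p.subject_id]["er_drug_effect"] for p in design.subjects])
    er_z = standardise(er_fx) if n_subjects >= 2 and np.std(er_fx) > 0 else er_fx
    for plan, z in zip(design.subjects, er_z):
        subj_fx[plan.subject_id]["er_change_z"] = float(z)

    # Self-produced animations (per subject x session x word).
    self_jerk: dict[tuple, float] = {}
    for plan in design.subjects:
        fx = subj_fx[plan.subject_id]
        for treatment in ("PLA", "HAL"):
            for word in WORDS:
                lo, hi = WORD_SPEED_BAND[word]
                olo, ohi = WORD_OMEGA_BAND[word]
                speed = 0.5 * (lo + hi) * fx["speed_factor"]
                omega = 0.5 * (olo + ohi) * fx["omega_factor"]
                if treatment == "HAL":
                    speed *= params.self_speed_drug_scale
                    omega *= params.self_jerk_drug_scale
                anim_id = f"self_{plan.subject_id}_{treatment}_{word}"
                tr = generate_trajectory(
                    word,
                    (speed, speed * omega**2),
                    duration_s,
                    rate_hz,
                    seed=int(rng_self.integers(2**31)),
                    animation_id=anim_id,
                )
                trajectories[anim_id] = tr
                self_jerk[(plan.subject_id, word, treatment)] = kin.compute_mean_jerk(tr)

    # Viewed trials: stratified selection of 8 stimuli per word per session.
    trial_rows = []
    for plan in design.subjects:
        for day in (1, 2):
            treatment = plan.drug_order[day - 1]
            for word in WORDS:
                pool = stim_by_word[word]
                chosen = []
                per_stratum = POOL_PER_WORD // TRIALS_PER_WORD
                for s in range(TRIALS_PER_WORD):
                    idx = s * per_stratum + int(rng_trial.integers(per_stratum))
                    chosen.append(pool.iloc[idx])
                for k, stim in enumerate(chosen):
                    trial_rows.append(
                        {
                            "trial_id": f"{plan.subject_id}_d{day}_{word}_{k}",
                            "subject_id": plan.subject_id,
                            "day_index": day,
                            "treatment": treatment,
                            "arousal": plan.arousal_by_session[day - 1],
                            "baseline_wm": plan.baseline_wm,
                            "target_word": word,
                            "mental_state": mental_state_of(word),
                            "animation_id": stim["animation_id"],
                            "stimulus_mean_speed": stim["mean_speed"],
                            "stimulus_mean_jerk": stim["mean_jerk"],
                        }
                    )
    trials = pd.DataFrame(trial_rows)

    jd_records = kin.attach_jerk_differences(trials, self_jerk)
    trials["jerk_diff"] = [r.same_session_jerk_diff for r in jd_records]
    trials["pla_jerk_diff"] = [r.placebo_jerk_diff for r in jd_records]
    hal_jerk = {
        (s, w): self_jerk[(s, w, "HAL")]
        for s in (p.subject_id for p in design.subjects)
        for w in WORDS
    }
    trials["hal_jerk_diff"] = [
        kin.jerk_difference(
            hal_jerk[(row.subject_id, row.target_word)], row.stimulus_mean_jerk
        )
        for row in trials.itertuples(index=False)
    ]

    # Slopes act on the placebo jerk difference centred *within word* and
    # scaled by one pooled SD: words occupy different kinematic bands, so an
    # uncentred predictor would be collinear with the mental-state category
    # (the named drug / mental-state parameters would no longer be marginal),
    # while a single pooled scale keeps the per-unit similarity slope uniform
    # across words.
    centred = (
        trials.groupby("target_word")["pla_jerk_diff"]
        .transform(lambda v: v - v.mean())
        .to_numpy()
    )
    jd_z = centred / np.std(centred, ddof=1)
    rating_cols: dict[str, list] = {f"rating_{w}": [] for w in WORDS}
    for i, row in enumerate(trials.itertuples(index=False)):
        fx = dict(subj_fx[row.subject_id])
        fx["animation_intercept"] = anim_intercepts[row.animation_id]
        ctx = {
            "treatment": row.treatment,
            "mental_state": row.mental_state,
            "target_word": row.target_word,
            "jerk_diff_z": float(jd_z[i]),
        }
        a = latent_accuracy(ctx, params, fx, rng_trial)
        ratings = ratings_from_accuracy(
            a, row.target_word, rng_trial, min(0.4, params.residual_sd)
        )
        for w in WORDS:
            rating_cols[f"rating_{w}"].append(ratings[w])
    for col, vals in rating_cols.items():
        trials[col] = vals

    # Auxiliary streams.
    er_frames, wm_frames, walk_rows = [], [], []
    session_rows = []
    for plan in design.subjects:
        for day in (1, 2):
            treatment = plan.drug_order[day - 1]
            er, wm, walk = generate_auxiliary(
                plan, treatment, params, subj_fx[plan.subject_id], rng_aux
            )
            er["day_index"] = day
            wm["day_index"] = day
            er_frames.append(er)
            wm_frames.append(wm)
            for pt in walk.pass_times:
                walk_rows.append(
                    {
                        "subject_id": plan.subject_id,
                        "day_index": day,
                        "treatment": treatment,
                        "pass_time_s": pt,
                        "pass_length_m": walk.pass_length_m,
                    }
                )
            session_rows.append(
                {
                    "subject_id": plan.subject_id,
                    "day_index": day,
                    "treatment": treatment,
                    "arousal": plan.arousal_by_session[day - 1],
                    "n_animation_trials": int(
                        (
                            (trials["subject_id"] == plan.subject_id)
                            & (trials["day_index"] == day)
                        ).sum()
                    ),
                    "n_emotion_trials": len(er),
                }
            )

    subjects = pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in design.subjects],
            "drug_day1": [p.drug_order[0] for p in design.subjects],
            "drug_day2": [p.drug_order[1] for p in design.subjects],
            "baseline_wm": [p.baseline_wm for p in design.subjects],
        }
    )
    return Cohort(
        design=design,
        params=params,
        subjects=subjects,
        sessions=pd.DataFrame(session_rows),
        animation_trials=trials,
        emotion_trials=pd.concat(er_frames, ignore_index=True),
        wm_trials=pd.concat(wm_frames, ignore_index=True),
        walk=pd.DataFrame(walk_rows),
        trajectories=trajectories,
        stimulus_kinematics=stim_kin,
    )
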