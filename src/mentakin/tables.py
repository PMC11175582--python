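"""Assembly of the three analysis tables the models are fitted to.

* trial table — one row per viewed animation (accuracy, drug, mental state,
  jerk-difference predictors, arousal, baseline WM and its median split);
* change table — one row per subject x word (percentage-accuracy change,
  ER change, WM change);
* walk table — one row per subject x session (mean walking speed, baseline WM).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import scoring
from .errors import SchemaError
from .kinematics import walking_speed


def wm_median_split(subjects: pd.DataFrame) -> pd.Series:
    """'low'/'high' baseline-WM group per subject (<= median is low)."""
    med = subjects["baseline_wm"].median()
    return pd.Series(
        np.where(subjects["baseline_wm"] <= med, "low", "high"),
        index=subjects["subject_id"],
        name="wm_group",
    )


def trial_table(
    animation_trials: pd.DataFrame, subjects: pd.DataFrame
) -> pd.DataFrame:
    """Scored trial-level analysis table."""
    scored = scoring.score_trials(animation_trials)
    groups = wm_median_split(subjects)
    scored = scored.merge(
        groups.rename("wm_group"), left_on="subject_id", right_index=True
    )
    return scored


def session_measures(
    emotion_trials: pd.DataFrame, wm_trials: pd.DataFrame
) -> pd.DataFrame:
    """Per subject x treatment ER and WM accuracy."""
    if "er_accuracy" not in emotion_trials:
        raise SchemaError("emotion trial table lacks er_accuracy")
    er = (
        emotion_trials.groupby(["subject_id", "treatment"])["er_accuracy"]
        .mean()
        .reset_index()
    )
    wm = (
        wm_trials.groupby(["subject_id", "treatment"])["correct"]
        .mean()
        .reset_index()
        .rename(columns={"correct": "wm_accuracy"})
    )
    return er.merge(wm, on=["subject_id", "treatment"])


def change_table(
    scored_trials: pd.DataFrame,
    emotion_trials: pd.DataFrame,
    wm_trials: pd.DataFrame,
) -> pd.DataFrame:
    """Subject x word change-score table for the truncated-t models."""
    meas = session_measures(emotion_trials, wm_trials)
    return scoring.change_score_table(scored_trials, meas)


def walk_table(walk: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Session-level mean walking speed with baseline WM covariates."""
    rows = []
    for (subj, treat), grp in walk.groupby(["subject_id", "treatment"]):
        rows.append(
            {
                "subject_id": subj,
                "treatment": treat,
                "speed": walking_speed(
                    grp["pass_time_s"].tolist(),
                    float(grp["pass_length_m"].iloc[0]),
                ),
            }
        )
    out = pd.DataFrame(rows)
    out = out.merge(subjects[["subject_id", "baseline_wm"]], on="subject_id")
    groups = wm_median_split(subjects)
    return out.merge(groups.rename("wm_group"), left_on="subject_id", right_index=True)
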