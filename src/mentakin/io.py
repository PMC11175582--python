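"""Reading and writing the delimited-text cohort and results files.

All tables are UTF-8 comma-separated with a header row; missing values are
empty fields.  Trajectories travel in one long-format file
(animation_id, word, agent, frame, t_s, x, y).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import PipelineError
from .synthetic import Cohort

COHORT_FILES = (
    "subjects.csv",
    "sessions.csv",
    "animation_trials.csv",
    "emotion_trials.csv",
    "wm_trials.csv",
    "walk.csv",
    "trajectories.csv",
)

#: Generator-internal columns stripped before writing the raw trial file:
#: downstream stages must recompute them from trajectories and ratings.
_DERIVED_TRIAL_COLS = ("jerk_diff", "pla_jerk_diff", "hal_jerk_diff")


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict:
    """Write the cohort's raw streams; returns {filename: path}."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    trials = cohort.animation_trials.drop(
        columns=[c for c in _DERIVED_TRIAL_COLS if c in cohort.animation_trials]
    )
    frames = {
        "subjects.csv": cohort.subjects,
        "sessions.csv": cohort.sessions,
        "animation_trials.csv": trials,
        "emotion_trials.csv": cohort.emotion_trials,
        "wm_trials.csv": cohort.wm_trials,
        "walk.csv": cohort.walk,
        "trajectories.csv": cohort.trajectories_frame(),
    }
    paths = {}
    for name, frame in frames.items():
        path = out / name
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


def read_table(directory: str | Path, name: str) -> pd.DataFrame:
    path = Path(directory) / name
    if not path.exists():
        raise PipelineError(f"expected file {path} is missing")
    return pd.read_csv(path)
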