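"""Kinematic summaries and jerk-difference predictors from raw trajectories.

Reads trajectories.csv from the cohort directory, computes mean speed and
mean jerk per animation (finite differences on the positional series), links
every viewed trial to the observer's own animations of the same word, and
writes kinematics.csv and jerk_differences.csv (same-session, placebo-based
and haloperidol-based similarity per trial).
"""

import argparse
from pathlib import Path

import pandas as pd

from mentakin.pipeline import stage_kinematics

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
args = parser.parse_args()

paths = stage_kinematics(args.cohort)
kin = pd.read_csv(paths["kinematics.csv"])
stim = kin[kin["animation_id"].str.startswith("stim_")]
print(f"summarised {len(kin)} animations ({len(stim)} stimuli)")
print("stimulus mean speed range: "
      f"{stim['mean_speed'].min():.0f}–{stim['mean_speed'].max():.0f} canvas units/s")
jd = pd.read_csv(paths["jerk_differences.csv"])
print(f"jerk differences for {len(jd)} trials; "
      f"median same-session {jd['same_session'].median():.0f}, "
      f"median placebo-based {jd['placebo_based'].median():.0f}")
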