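"""Trial accuracy, percentage accuracy and change scores.

Builds the three analysis tables from the raw cohort files: the trial-level
accuracy table (target rating minus mean non-target rating, binary correct
flag, jerk-difference predictors), the subject-by-word change-score table
(haloperidol minus placebo percentage accuracy, with emotion-recognition and
working-memory changes), and the session-level walking-speed table.
"""

import argparse
from pathlib import Path

import pandas as pd

from mentakin.pipeline import stage_score

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
args = parser.parse_args()

paths = stage_score(args.cohort)
scores = pd.read_csv(paths["scores.csv"])
by_drug = scores.groupby(["treatment", "mental_state"])["accuracy"].mean().round(2)
print("mean accuracy by treatment and mental state:")
print(by_drug.to_string())
changes = pd.read_csv(paths["change_scores.csv"])
print(f"\nchange scores for {len(changes)} subject-word cells; "
      f"mean accuracy change {changes['accuracy_change'].mean():+.3f}")
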