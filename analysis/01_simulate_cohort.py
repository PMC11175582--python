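"""Generate the synthetic crossover cohort and write its raw data streams.

Thin driver over mentakin.pipeline.stage_simulate: 33 subjects, two
counterbalanced haloperidol/placebo sessions each, with self-produced and
viewed triangle animations, emotion-recognition, working-memory and walking
streams.  Trajectories are simulated at reduced temporal resolution (the
kinematic summaries do not depend on it); pass --full-resolution to write
35 s / 133 Hz paths instead.
"""

import argparse
from pathlib import Path

from mentakin.pipeline import RunConfig, stage_simulate

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/cohort"))
parser.add_argument("--n-subjects", type=int, default=33)
parser.add_argument("--full-resolution", action="store_true")
args = parser.parse_args()

config = RunConfig(
    seed=args.seed,
    n_subjects=args.n_subjects,
    output_dir=str(args.out),
    duration_s=35.0 if args.full_resolution else 3.0,
    rate_hz=133.0 if args.full_resolution else 50.0,
)
args.out.mkdir(parents=True, exist_ok=True)
paths = stage_simulate(config, args.out)
print(f"wrote {len(paths)} cohort files to {args.out}:")
for name in sorted(paths):
    print(f"  {name}")
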