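"""End-to-end orchestration: simulate → kinematics → score → fit → compare.

Stage contracts are file-based: every stage reads only the delimited-text
outputs of earlier stages from the run directory and writes its own, so each
stage can be re-run standalone.  A manifest records the configuration hash,
checksums of all outputs and wall times; deterministic stages reproduce
identical checksums under an identical configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, tables
from .errors import PipelineError, RegistryError, ReportError
from .formulas import REGISTRY, build_model
from .inference import SamplerSettings, compare, fit, summary_table
from .kinematics import attach_jerk_differences, summarise_table, trajectories_from_frame
from .synthetic import GeneratorParams, generate_cohort

log = logging.getLogger("mentakin")

_SELF_ID = re.compile(r"^self_(?P<subject>[^_]+)_(?P<treatment>HAL|PLA)_(?P<word>\w+)$")


@dataclass
class RunConfig:
    seed: int = 0
    n_subjects: int = 33
    cohort: GeneratorParams = field(default_factory=GeneratorParams)
    models_to_fit: tuple = ("1.1", "1.2")
    comparisons: tuple = ()  # tuples of model names fitted to the same table
    output_dir: str = "results/run"
    log_level: str = "INFO"
    duration_s: float = 35.0
    rate_hz: float = 133.0
    sampler: SamplerSettings = field(default_factory=SamplerSettings)

    def validate(self) -> None:
        unknown = [m for m in self.models_to_fit if m not in REGISTRY]
        for group in self.comparisons:
            unknown += [m for m in group if m not in REGISTRY]
        if unknown:
            raise RegistryError(f"unknown models in config: {sorted(set(unknown))}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = dataclasses.asdict(self.cohort)
        d["sampler"] = dataclasses.asdict(self.sampler)
        d["models_to_fit"] = list(self.models_to_fit)
        d["comparisons"] = [list(g) for g in self.comparisons]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = GeneratorParams(**d["cohort"])
        if "sampler" in d and isinstance(d["sampler"], dict):
            d["sampler"] = SamplerSettings(**d["sampler"])
        for key in ("models_to_fit",):
            if key in d:
                d[key] = tuple(d[key])
        if "comparisons" in d:
            d["comparisons"] = tuple(tuple(g) for g in d["comparisons"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    checksums: dict
    wall_times: dict

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, outdir: Path) -> dict:
    cohort = generate_cohort(
        config.n_subjects,
        params=config.cohort,
        seed=config.seed,
        duration_s=config.duration_s,
        rate_hz=config.rate_hz,
    )
    return io.write_cohort(cohort, outdir)


def stage_kinematics(outdir: Path) -> dict:
    """trajectories.csv → kinematics.csv + jerk_differences.csv."""
    traj = io.read_table(outdir, "trajectories.csv")
    summaries = summarise_table(trajectories_from_frame(traj))
    kin_path = outdir / "kinematics.csv"
    summaries.to_csv(kin_path, index=False)

    trials = io.read_table(outdir, "animation_trials.csv")
    jerk = dict(zip(summaries["animation_id"], summaries["mean_jerk"]))
    self_jerk = {}
    for anim_id, value in jerk.items():
        m = _SELF_ID.match(str(anim_id))
        if m:
            self_jerk[(m["subject"], m["word"], m["treatment"])] = value
    trials = trials.assign(
        stimulus_mean_jerk=[jerk[a] for a in trials["animation_id"]]
    )
    records = attach_jerk_differences(trials, self_jerk)
    hal_self = {(s, w): v for (s, w, t), v in self_jerk.items() if t == "HAL"}
    jd = pd.DataFrame(
        {
            "trial_id": [r.trial_id for r in records],
            "same_session": [r.same_session_jerk_diff for r in records],
            "placebo_based": [r.placebo_jerk_diff for r in records],
            "hal_based": [
                abs(hal_self[(row.subject_id, row.target_word)] - row.stimulus_mean_jerk)
                for row in trials.itertuples(index=False)
            ],
        }
    )
    jd_path = outdir / "jerk_differences.csv"
    jd.to_csv(jd_path, index=False)
    return {"kinematics.csv": kin_path, "jerk_differences.csv": jd_path}


def stage_score(outdir: Path) -> dict:
    """Raw trials + jerk differences → scores.csv, change_scores.csv, walk_sessions.csv."""
    trials = io.read_table(outdir, "animation_trials.csv")
    subjects = io.read_table(outdir, "subjects.csv")
    jd = io.read_table(outdir, "jerk_differences.csv")
    scored = tables.trial_table(trials, subjects)
    scored = scored.merge(jd, on="trial_id", how="left")
    if scored[["same_session", "placebo_based"]].isna().any().any():
        raise PipelineError(
            "score stage: jerk_differences.csv (kinematics stage) does not "
            "cover every trial in animation_trials.csv (simulate stage)"
        )
    scored = scored.rename(
        columns={
            "same_session": "jerk_diff",
            "placebo_based": "pla_jerk_diff",
            "hal_based": "hal_jerk_diff",
        }
    )
    emotion = io.read_table(outdir, "emotion_trials.csv")
    wm = io.read_table(outdir, "wm_trials.csv")
    changes = tables.change_table(scored, emotion, wm)
    walk = tables.walk_table(io.read_table(outdir, "walk.csv"), subjects)
    paths = {}
    for name, frame in (
        ("scores.csv", scored),
        ("change_scores.csv", changes),
        ("walk_sessions.csv", walk),
    ):
        path = outdir / name
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


_TABLE_FILE = {
    "trials": "scores.csv",
    "changes": "change_scores.csv",
    "walk": "walk_sessions.csv",
}


def load_model_table(outdir: Path, model_name: str) -> pd.DataFrame:
    spec = build_model(model_name)
    return io.read_table(outdir, _TABLE_FILE[spec.table])


def stage_fit(config: RunConfig, outdir: Path) -> tuple:
    fits = {}
    paths = {}
    for i, name in enumerate(config.models_to_fit):
        table = load_model_table(outdir, name)
        f = fit(name, table, seed=config.seed + 1000 + i, settings=config.sampler)
        fits[name] = f
        path = outdir / f"model_{name.replace('.', '_')}_summary.csv"
        summary_table(f).to_csv(path, index=False)
        paths[path.name] = path
        log.info("fitted model %s (max Rhat %.3f)", name, f.max_rhat)
    return fits, paths


def stage_compare(config: RunConfig, fits: dict, outdir: Path) -> dict:
    frames = []
    for group in config.comparisons:
        missing = [m for m in group if m not in fits]
        if missing:
            raise PipelineError(
                f"comparison {group} requires models {missing} in models_to_fit"
            )
        result = compare({m: fits[m] for m in group})
        frame = result.as_frame()
        frame.insert(0, "comparison", "+".join(group))
        frames.append(frame)
    if not frames:
        return {}
    path = outdir / "comparison.csv"
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return {"comparison.csv": path}


def run_all(config: RunConfig) -> RunManifest:
    """Execute every stage in order; any failure aborts with a stage-named error."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksums: dict = {}
    wall: dict = {}
    stages = [
        ("simulate", lambda: stage_simulate(config, outdir)),
        ("kinematics", lambda: stage_kinematics(outdir)),
        ("score", lambda: stage_score(outdir)),
    ]
    fits_holder: dict = {}

    def _fit():
        fits, paths = stage_fit(config, outdir)
        fits_holder.update(fits)
        return paths

    stages.append(("fit", _fit))
    stages.append(("compare", lambda: stage_compare(config, fits_holder, outdir)))

    for name, fn in stages:
        t0 = time.time()
        try:
            paths = fn()
        except Exception as exc:  # noqa: BLE001 — re-raise with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        wall[name] = round(time.time() - t0, 3)
        for fname, path in paths.items():
            checksums[fname] = _checksum(Path(path))
        log.info("stage %s done in %.2fs", name, wall[name])

    manifest = RunManifest(
        config_hash=config.config_hash(),
        version=__version__,
        checksums=checksums,
        wall_times=wall,
    )
    manifest.write(outdir / "manifest.json")
    return manifest


def report(results_dir: str | Path) -> str:
    """Markdown report of all model summaries plus any comparison table."""
    outdir = Path(results_dir)
    summaries = sorted(outdir.glob("model_*_summary.csv"))
    if not summaries:
        raise ReportError(f"no model summaries found in {outdir}")
    lines = ["# Model summaries", ""]
    for path in summaries:
        name = path.stem.replace("model_", "").replace("_summary", "").replace("_", ".")
        frame = pd.read_csv(path)
        lines.append(f"## Model {name}")
        lines.append("")
        lines.append("```\n" + frame.round(3).to_string(index=False) + "\n```")
        lines.append("")
    cmp_path = outdir / "comparison.csv"
    if cmp_path.exists():
        lines.append("## Model comparison (PSIS-LOO)")
        lines.append("")
        lines.append("```\n" + pd.read_csv(cmp_path).round(3).to_string(index=False) + "\n```")
        lines.append("")
    text = "\n".join(lines)
    (outdir / "report.md").write_text(text, encoding="utf-8")
    return text
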