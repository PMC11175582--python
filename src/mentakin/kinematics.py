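"""Speed and jerk summaries of two-agent trajectories, and derived similarity indices.

The central quantity is *mean jerk*: the average Euclidean magnitude of the
third time-derivative of position, estimated by central finite differences on
uniformly sampled positional data.  Jerk similarity between an observer's own
animation of a word and a viewed stimulus of the same word is the absolute
difference of the two mean-jerk values ("jerk difference"); lower values mean
the observer moves more like the original animator.  Walking speed is the mean
over passes of pass length divided by pass time.

Differentiation uses central stencils evaluated on interior frames only
(boundary frames where the stencil does not fit are dropped), with no
smoothing: fourth-order accuracy for velocity, second-order for jerk.  On
polynomials up to degree 3 the jerk estimate is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import (
    InsufficientDataError,
    LinkageError,
    MentakinError,
    SamplingError,
)

#: Relative timestamp jitter tolerated before sampling is declared non-uniform.
JITTER_TOLERANCE = 0.01


@dataclass(frozen=True)
class Trajectory:
    """Positional time series for the two animated triangles.

    ``t`` has shape ``(n_frames,)`` (seconds, strictly increasing);
    ``xy`` has shape ``(2, n_frames, 2)``: agent, frame, (x, y) in canvas units.
    """

    animation_id: str
    word: str
    t: np.ndarray
    xy: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        xy = np.asarray(self.xy, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "xy", xy)
        if xy.ndim != 3 or xy.shape[0] != 2 or xy.shape[2] != 2:
            raise MentakinError(
                f"trajectory {self.animation_id!r}: xy must have shape (2, n, 2), got {xy.shape}"
            )
        if t.shape != (xy.shape[1],):
            raise MentakinError(
                f"trajectory {self.animation_id!r}: t and xy frame counts differ"
            )
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise MentakinError(
                f"trajectory {self.animation_id!r}: timestamps must strictly increase"
            )

    @property
    def n_frames(self) -> int:
        return int(self.t.size)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (animation_id, agent, frame, t_s, x, y)."""
        n = self.n_frames
        return pd.DataFrame(
            {
                "animation_id": np.repeat(self.animation_id, 2 * n),
                "word": np.repeat(self.word, 2 * n),
                "agent": np.repeat([0, 1], n),
                "frame": np.tile(np.arange(n), 2),
                "t_s": np.tile(self.t, 2),
                "x": self.xy[:, :, 0].ravel(),
                "y": self.xy[:, :, 1].ravel(),
            }
        )


@dataclass(frozen=True)
class KinematicSummary:
    """Per-animation kinematic summary in canvas units / s^k."""

    animation_id: str
    mean_speed: float
    mean_jerk: float


@dataclass(frozen=True)
class JerkDifferenceRecord:
    """Observer–animator jerk similarity for one viewed animation trial.

    ``same_session_jerk_diff`` compares the stimulus against the observer's
    own animation from the trial's session.  ``placebo_jerk_diff`` always uses
    the observer's placebo-session animation; for placebo trials the two
    coincide by construction.
    """

    trial_id: str
    same_session_jerk_diff: float
    placebo_jerk_diff: float


@dataclass(frozen=True)
class WalkRecord:
    """Timed 10 m walking passes for one session."""

    subject_id: str
    treatment: str
    pass_times: tuple = field(default_factory=tuple)
    pass_length_m: float = 10.0

    @property
    def mean_speed_mps(self) -> float:
        return walking_speed(list(self.pass_times), self.pass_length_m)


def _uniform_dt(t: np.ndarray) -> float:
    """Mean sampling interval; raises if jitter exceeds tolerance."""
    dt = np.diff(t)
    mean_dt = float(dt.mean())
    if mean_dt <= 0:
        raise SamplingError("non-increasing timestamps")
    if np.max(np.abs(dt - mean_dt)) > JITTER_TOLERANCE * mean_dt:
        raise SamplingError(
            "timestamps deviate from uniform sampling by more than "
            f"{JITTER_TOLERANCE:.0%} of the mean interval"
        )
    return mean_dt


def _velocity(pos: np.ndarray, dt: float) -> np.ndarray:
    """Central-difference velocity, shape (n_interior, 2).

    Uses the fourth-order five-point stencil when enough frames exist, else
    the second-order two-point central stencil; endpoints are dropped.
    """
    n = pos.shape[0]
    if n >= 5:
        v = (-pos[4:] + 8 * pos[3:-1] - 8 * pos[1:-3] + pos[:-4]) / (12 * dt)
        return v
    return (pos[2:] - pos[:-2]) / (2 * dt)


def _maybe_smooth(pos: np.ndarray, smooth: bool) -> np.ndarray:
    """Optional Savitzky–Golay pre-filter (window 7, order 3), OFF by default.

    Raw positional data are the canonical input; the filter exists for noisy
    capture devices and preserves polynomials up to the filter order.
    """
    if not smooth or pos.shape[0] < 7:
        return pos
    return savgol_filter(pos, window_length=7, polyorder=3, axis=0)


def compute_mean_speed(trajectory: Trajectory, smooth: bool = False) -> float:
    """Mean over interior frames and both agents of |velocity|.

    Velocity is the central finite difference of position; a static
    trajectory returns exactly 0.
    """
    if trajectory.n_frames < 2:
        raise InsufficientDataError("mean speed requires at least 2 frames")
    if trajectory.n_frames == 2:
        dt = float(trajectory.t[1] - trajectory.t[0])
        v = (trajectory.xy[:, 1, :] - trajectory.xy[:, 0, :]) / dt
        return float(np.mean(np.linalg.norm(v, axis=-1)))
    dt = _uniform_dt(trajectory.t)
    speeds = [
        np.linalg.norm(_velocity(_maybe_smooth(trajectory.xy[a], smooth), dt), axis=-1)
        for a in range(2)
    ]
    return float(np.mean(np.concatenate(speeds)))


def compute_mean_jerk(trajectory: Trajectory, smooth: bool = False) -> float:
    """Mean magnitude of the third derivative of position.

    Third-order central differences on interior frames (two boundary frames
    dropped at each end); per-frame magnitude is the Euclidean norm over
    (x, y); the mean pools frames and both agents.  Exact for cubic paths.
    """
    if trajectory.n_frames < 4:
        raise InsufficientDataError("mean jerk requires at least 4 frames")
    dt = _uniform_dt(trajectory.t)
    mags = []
    for a in range(2):
        pos = _maybe_smooth(trajectory.xy[a], smooth)
        if pos.shape[0] >= 5:
            j = (pos[4:] - 2 * pos[3:-1] + 2 * pos[1:-3] - pos[:-4]) / (2 * dt**3)
        else:
            # 4 frames: one-sided third difference, exact on cubics too.
            j = (pos[3:] - 3 * pos[2:-1] + 3 * pos[1:-2] - pos[:-3]) / dt**3
        mags.append(np.linalg.norm(j, axis=-1))
    return float(np.mean(np.concatenate(mags)))


def summarise(trajectory: Trajectory) -> KinematicSummary:
    return KinematicSummary(
        animation_id=trajectory.animation_id,
        mean_speed=compute_mean_speed(trajectory),
        mean_jerk=compute_mean_jerk(trajectory),
    )


def jerk_difference(self_mean_jerk: float, stimulus_mean_jerk: float) -> float:
    """|self − stimulus| mean jerk: the observer–animator similarity index."""
    a, b = float(self_mean_jerk), float(stimulus_mean_jerk)
    if not (np.isfinite(a) and np.isfinite(b)):
        raise MentakinError("jerk values must be finite")
    if a < 0 or b < 0:
        raise MentakinError("mean jerk values are non-negative by definition")
    return abs(a - b)


def attach_jerk_differences(
    trials: pd.DataFrame,
    self_jerk_by_word_session: Mapping[tuple, float],
) -> list[JerkDifferenceRecord]:
    """Link each viewed trial to the observer's own animations of its word.

    ``trials`` needs columns trial_id, subject_id, treatment, target_word and
    stimulus_mean_jerk.  ``self_jerk_by_word_session`` maps
    ``(subject_id, word, treatment)`` to the observer's own mean jerk.  The
    same-session index uses the trial's treatment; the placebo-based index
    always uses the PLA entry (so both agree on placebo trials).
    """
    records = []
    for row in trials.itertuples(index=False):
        key_same = (row.subject_id, row.target_word, row.treatment)
        key_pla = (row.subject_id, row.target_word, "PLA")
        for key in (key_same, key_pla):
            if key not in self_jerk_by_word_session:
                raise LinkageError(
                    f"no self-produced animation for subject {key[0]!r}, "
                    f"word {key[1]!r}, session {key[2]!r}"
                )
        records.append(
            JerkDifferenceRecord(
                trial_id=row.trial_id,
                same_session_jerk_diff=jerk_difference(
                    self_jerk_by_word_session[key_same], row.stimulus_mean_jerk
                ),
                placebo_jerk_diff=jerk_difference(
                    self_jerk_by_word_session[key_pla], row.stimulus_mean_jerk
                ),
            )
        )
    return records


def walking_speed(pass_times: Sequence[float], pass_length_m: float = 10.0) -> float:
    """Mean over passes of pass_length / pass_time, in m/s."""
    times = np.asarray(list(pass_times), dtype=float)
    if times.size == 0:
        raise MentakinError("walking speed requires at least one pass")
    if np.any(times <= 0):
        raise MentakinError("pass times must be positive")
    if pass_length_m <= 0:
        raise MentakinError("pass length must be positive")
    return float(np.mean(pass_length_m / times))


# ---------------------------------------------------------------------------
# Table-level interfaces (long-format trajectories.csv <-> summaries)
# ---------------------------------------------------------------------------

def trajectories_from_frame(frame: pd.DataFrame) -> list[Trajectory]:
    """Rebuild Trajectory objects from the long-format table."""
    out = []
    for anim_id, grp in frame.groupby("animation_id", sort=False):
        word = str(grp["word"].iloc[0]) if "word" in grp else ""
        a0 = grp[grp["agent"] == 0].sort_values("frame")
        a1 = grp[grp["agent"] == 1].sort_values("frame")
        t = a0["t_s"].to_numpy()
        xy = np.stack(
            [a0[["x", "y"]].to_numpy(), a1[["x", "y"]].to_numpy()], axis=0
        )
        rate = 1.0 / float(np.mean(np.diff(t))) if t.size > 1 else 0.0
        out.append(Trajectory(str(anim_id), word, t, xy, rate))
    return out


def summarise_table(trajectories: Iterable[Trajectory]) -> pd.DataFrame:
    """kinematics.csv: one row (animation_id, mean_speed, mean_jerk) per animation."""
    rows = [summarise(tr) for tr in trajectories]
    return pd.DataFrame(
        {
            "animation_id": [r.animation_id for r in rows],
            "mean_speed": [r.mean_speed for r in rows],
            "mean_jerk": [r.mean_jerk for r in rows],
        }
    )
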