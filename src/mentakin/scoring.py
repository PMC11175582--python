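"""Animations-task accuracy statistics, change scores, and predictor scaling.

A trial presents one target word and four rating scales (1–10).  Continuous
accuracy is the target rating minus the mean of the three non-target ratings
(range −9..9): positive values mean the target word was discriminated from
the foils.  The binary transformation calls a trial correct when the target
received the strictly highest rating; percentage accuracy is the fraction of
the 8 trials of one word in one session that were correct; change scores are
haloperidol minus placebo throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CardinalityError,
    DegeneratePredictorError,
    MalformedTrialError,
    MentakinError,
)

WORDS = ("seducing", "surprising", "following", "fighting")
MENTAL_WORDS = frozenset({"seducing", "surprising"})

TRIALS_PER_WORD = 8


def mental_state_of(word: str) -> str:
    """'mental' for seducing/surprising, 'nonmental' for following/fighting."""
    if word not in WORDS:
        raise MalformedTrialError(f"unknown animation word {word!r}")
    return "mental" if word in MENTAL_WORDS else "nonmental"


def _validate_ratings(ratings: Mapping[str, float], target_word: str) -> None:
    if set(ratings) != set(WORDS):
        raise MalformedTrialError(
            f"ratings must cover exactly the four words, got {sorted(ratings)}"
        )
    if target_word not in ratings:
        raise MalformedTrialError(f"target word {target_word!r} has no rating")
    for w, r in ratings.items():
        if not (1.0 <= float(r) <= 10.0):
            raise MalformedTrialError(f"rating for {w!r} outside [1, 10]: {r}")


def accuracy_score(ratings: Mapping[str, float], target_word: str) -> float:
    """Target rating minus the mean of the three non-target ratings."""
    _validate_ratings(ratings, target_word)
    non_targets = [float(ratings[w]) for w in WORDS if w != target_word]
    return float(ratings[target_word]) - float(np.mean(non_targets))


def binary_correct(ratings: Mapping[str, float], target_word: str) -> bool:
    """True iff the target received the strictly highest rating (ties fail)."""
    _validate_ratings(ratings, target_word)
    target = float(ratings[target_word])
    return all(target > float(ratings[w]) for w in WORDS if w != target_word)


def percentage_accuracy(correct: Sequence[bool]) -> float:
    """Fraction correct out of the 8 trials of one word in one session."""
    if len(correct) != TRIALS_PER_WORD:
        raise CardinalityError(
            f"percentage accuracy is defined over exactly {TRIALS_PER_WORD} "
            f"trials, got {len(correct)}"
        )
    return float(np.sum([bool(c) for c in correct])) / TRIALS_PER_WORD


@dataclass(frozen=True)
class ChangeScores:
    """Per subject-by-word drug-minus-placebo deltas."""

    subject_id: str
    word: str
    animations_accuracy_change: float
    er_change: float
    wm_change: float


def change_scores(
    subject_id: str,
    word: str,
    hal_pct: float,
    pla_pct: float,
    er_hal: float,
    er_pla: float,
    wm_hal: float,
    wm_pla: float,
) -> ChangeScores:
    """HAL − PLA for animations percentage accuracy, ER and WM accuracy."""
    for name, v in (("hal_pct", hal_pct), ("pla_pct", pla_pct)):
        if not (0.0 <= v <= 1.0):
            raise MentakinError(f"{name} must lie in [0, 1], got {v}")
    return ChangeScores(
        subject_id=subject_id,
        word=word,
        animations_accuracy_change=float(hal_pct) - float(pla_pct),
        er_change=float(er_hal) - float(er_pla),
        wm_change=float(wm_hal) - float(wm_pla),
    )


def standardise(values: Sequence[float]) -> np.ndarray:
    """z-score with the sample (n−1) standard deviation.

    Raises for constant input, which would otherwise silently produce NaNs in
    a design matrix.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise DegeneratePredictorError("standardise needs at least 2 values")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegeneratePredictorError("cannot standardise a constant predictor")
    return (x - float(np.mean(x))) / sd


# ---------------------------------------------------------------------------
# Table-level interfaces
# ---------------------------------------------------------------------------

RATING_COLS = {w: f"rating_{w}" for w in WORDS}


def score_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Append accuracy and correct columns to an animation-trial table.

    Expects columns ``target_word`` and ``rating_<word>`` for each of the
    four words.
    """
    missing = [c for c in RATING_COLS.values() if c not in trials.columns]
    if missing:
        raise MalformedTrialError(f"trial table missing rating columns {missing}")
    acc, corr = [], []
    for row in trials.itertuples(index=False):
        ratings = {w: getattr(row, RATING_COLS[w]) for w in WORDS}
        acc.append(accuracy_score(ratings, row.target_word))
        corr.append(binary_correct(ratings, row.target_word))
    out = trials.copy()
    out["accuracy"] = acc
    out["correct"] = corr
    out["mental_state"] = [mental_state_of(w) for w in out["target_word"]]
    return out


def percentage_accuracy_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Subject × word × treatment percentage accuracy from scored trials."""
    rows = []
    grouped = scored.groupby(["subject_id", "target_word", "treatment"], sort=True)
    for (subj, word, treat), grp in grouped:
        rows.append(
            {
                "subject_id": subj,
                "word": word,
                "treatment": treat,
                "pct_accuracy": percentage_accuracy(list(grp["correct"])),
            }
        )
    return pd.DataFrame(rows)


def change_score_table(
    scored: pd.DataFrame, session_measures: pd.DataFrame
) -> pd.DataFrame:
    """Subject × word change-score table (animations, ER, WM).

    ``session_measures`` carries one row per subject × treatment with columns
    er_accuracy and wm_accuracy.
    """
    pct = percentage_accuracy_table(scored)
    wide = pct.pivot_table(
        index=["subject_id", "word"], columns="treatment", values="pct_accuracy"
    ).reset_index()
    sess = session_measures.pivot_table(
        index="subject_id", columns="treatment", values=["er_accuracy", "wm_accuracy"]
    )
    rows = []
    for row in wide.itertuples(index=False):
        subj = row.subject_id
        cs = change_scores(
            subject_id=subj,
            word=row.word,
            hal_pct=row.HAL,
            pla_pct=row.PLA,
            er_hal=float(sess.loc[subj, ("er_accuracy", "HAL")]),
            er_pla=float(sess.loc[subj, ("er_accuracy", "PLA")]),
            wm_hal=float(sess.loc[subj, ("wm_accuracy", "HAL")]),
            wm_pla=float(sess.loc[subj, ("wm_accuracy", "PLA")]),
        )
        rows.append(
            {
                "subject_id": cs.subject_id,
                "word": cs.word,
                "mental_state": mental_state_of(cs.word),
                "accuracy_change": cs.animations_accuracy_change,
                "er_change": cs.er_change,
                "wm_change": cs.wm_change,
            }
        )
    return pd.DataFrame(rows)
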