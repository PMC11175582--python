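"""Model registry and design-matrix construction.

The seventeen registered models form three families over three analysis
tables:

* trial-level accuracy models (Gaussian, and 2-component Gaussian-mixture
  variants) with subject and animation random effects;
* subject-by-word change-score models with a Student-t response truncated to
  [−1, 1];
* session-level walking-speed models.

Dummy coding uses treatment contrasts with fixed reference levels (drug →
PLA, mental state → non-mental, drug day → day 1).  ``a * b`` expands to all
main effects and interactions, R-style.  Arousal enters as an ordered factor
with orthogonal polynomial contrasts up to degree 7 (capped at one less than
the number of observed levels).  Continuous predictors are z-scored over the
analysis table at design-build time; ``||`` random slopes are uncorrelated
with their group's intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import RegistryError, SchemaError
from .scoring import standardise

#: How each model variable is encoded.  Categorical entries carry
#: (table column, reference level, non-reference level -> dummy name).
CATEGORICAL = {
    "drug": ("treatment", "PLA", {"HAL": "drugHAL"}),
    "mental_state": ("mental_state", "nonmental", {"mental": "mental_statemental"}),
    "drug_day": ("day_index", 1, {2: "drug_day2"}),
}
#: Ordered-factor variables with orthogonal polynomial contrasts.
POLY = {"arousal": 7}
#: Continuous variables and the table columns they read from; anything not
#: listed in CATEGORICAL/POLY is treated as continuous and z-scored, with the
#: variable name doubling as the column name.
CONTINUOUS_ALIASES = {"wm": "baseline_wm"}

_POLY_SUFFIX = ["L", "Q", "C", "E4", "E5", "E6", "E7"]


@dataclass(frozen=True)
class RandomTerm:
    """One random-effects block: intercept or slope varying by a grouping factor."""

    group: str  # table column, e.g. "subject_id"
    slope: str | None = None  # variable name, e.g. "drug"; None = intercept
    correlated: bool = False  # "||" notation => False

    @property
    def label(self) -> str:
        short = self.group.replace("_id", "")
        if self.slope is None:
            return f"sd_{short}_Intercept"
        return f"sd_{short}_{self.slope}"


@dataclass(frozen=True)
class PriorSet:
    """Zero-centred priors: normal for coefficients, half-Cauchy for scales."""

    coefficient_scale: float = 2.5
    variance_scale: float = 2.5


@dataclass(frozen=True)
class ModelSpec:
    name: str
    response: str  # family: gaussian | gaussian_mixture_2 | student_t_truncated
    response_col: str
    fixed: str  # formula right-hand side, e.g. "drug * mental_state"
    random: tuple = ()
    truncation: tuple | None = None  # (lower, upper)
    priors: PriorSet = field(default_factory=PriorSet)
    table: str = "trials"  # trials | changes | walk
    subset: str | None = None  # pandas query applied before standardisation


_SUBJ_FULL = (RandomTerm("subject_id"), RandomTerm("subject_id", "drug"))
_ANIM = (RandomTerm("animation_id"),)
_SUBJ = (RandomTerm("subject_id"),)


def _registry() -> dict:
    reg = {}

    def add(name, **kw):
        reg[name] = ModelSpec(name=name, **kw)

    trial_gauss = dict(response="gaussian", response_col="accuracy", table="trials")
    add("1.1", fixed="drug", random=_SUBJ_FULL + _ANIM, **trial_gauss)
    add("1.2", fixed="drug * mental_state", random=_SUBJ_FULL + _ANIM, **trial_gauss)
    add("1.3", fixed="drug * drug_day", random=_SUBJ_FULL + _ANIM, **trial_gauss)
    add("1.4", fixed="drug * arousal", random=_SUBJ_FULL + _ANIM, **trial_gauss)
    add("2.1", fixed="drug * mental_state * jerk_diff", random=_SUBJ_FULL + _ANIM,
        **trial_gauss)
    add("2.2", fixed="jerk_diff * mental_state", random=_SUBJ + _ANIM,
        subset="treatment == 'PLA'", **trial_gauss)
    add("2.3", fixed="jerk_diff * mental_state", random=_SUBJ + _ANIM,
        subset="treatment == 'HAL'", **trial_gauss)
    add("3.1", fixed="drug * mental_state * pla_jerk_diff", random=_SUBJ_FULL + _ANIM,
        **trial_gauss)
    add("3.2", fixed="mental_state * pla_jerk_diff * hal_jerk_diff",
        random=_SUBJ + _ANIM, subset="treatment == 'HAL'", **trial_gauss)

    trunc = dict(
        response="student_t_truncated",
        response_col="accuracy_change",
        truncation=(-1.0, 1.0),
        table="changes",
    )
    add("4.1", fixed="er_change * mental_state + wm_change * mental_state", **trunc)
    add("4.2", fixed="er_change * mental_state", **trunc)

    mix = dict(response="gaussian_mixture_2", response_col="accuracy", table="trials")
    add("5", fixed="drug * mental_state", random=_SUBJ, **mix)
    add("6.1", fixed="drug * wm", random=_SUBJ, **mix)
    add("6.2", fixed="drug", random=_SUBJ, subset="wm_group == 'low'", **mix)
    add("6.3", fixed="drug", random=_SUBJ, subset="wm_group == 'high'", **mix)

    walk = dict(response="gaussian", response_col="speed", table="walk")
    add("7.1", fixed="drug * wm", random=_SUBJ, **walk)
    add("7.2", fixed="drug * wm", random=_SUBJ, subset="wm_group == 'low'", **walk)
    return reg


REGISTRY = _registry()


def build_model(name: str) -> ModelSpec:
    """Look up a registered model by its name (e.g. ``"2.1"``)."""
    try:
        return REGISTRY[str(name)]
    except KeyError:
        raise RegistryError(
            f"unknown model {name!r}; registered: {sorted(REGISTRY)}"
        ) from None


def make_spec(name: str, base: str | None = None, **overrides) -> ModelSpec:
    """Ad-hoc ModelSpec, optionally derived from a registered model.

    Useful for control fits such as intercept-only comparators or models with
    an extra pure-noise covariate.
    """
    if base is not None:
        spec = build_model(base)
        kw = {f.name: getattr(spec, f.name) for f in spec.__dataclass_fields__.values()}
    else:
        kw = dict(
            response="gaussian", response_col="accuracy", fixed="", random=(),
            truncation=None, priors=PriorSet(), table="trials", subset=None,
        )
    kw["name"] = name
    kw.update(overrides)
    return ModelSpec(**kw)


# ---------------------------------------------------------------------------
# Formula expansion
# ---------------------------------------------------------------------------

def expand_formula(fixed: str) -> list:
    """R-style expansion: ``a * b`` -> a, b, a:b.  Returns variable tuples."""
    terms: list[tuple] = []
    if not fixed.strip():
        return terms
    for chunk in fixed.split("+"):
        factors = [f.strip() for f in chunk.split("*") if f.strip()]
        for size in range(1, len(factors) + 1):
            for combo in combinations(factors, size):
                if combo not in terms:
                    terms.append(combo)
    rank = {c: i for i, c in enumerate(terms)}
    return sorted(terms, key=lambda c: (len(c), rank[c]))


def orthogonal_poly(x: np.ndarray, degree: int) -> tuple:
    """Orthogonal polynomial contrasts of a numeric vector (R ``poly`` style).

    Returns (matrix n x d, effective degree); columns are orthonormal over
    the data.  The degree is capped at (number of distinct values − 1).
    """
    x = np.asarray(x, dtype=float)
    d = int(min(degree, np.unique(x).size - 1))
    if d < 1:
        raise SchemaError("ordered factor needs at least 2 observed levels")
    xc = x - x.mean()
    raw = np.vander(xc, N=d + 1, increasing=True)
    q, _ = np.linalg.qr(raw)
    q = q[:, 1:]
    # QR sign is arbitrary; fix it so each column correlates positively with
    # the matching raw power (R's convention of positive leading coefficients).
    for j in range(q.shape[1]):
        if np.dot(q[:, j], xc ** (j + 1)) < 0:
            q[:, j] = -q[:, j]
        q[:, j] /= np.linalg.norm(q[:, j])
    return q, d


def _encode_variable(var: str, table: pd.DataFrame) -> list:
    """Encode one variable as [(column name, values array), ...]."""
    if var in CATEGORICAL:
        col, ref, levels = CATEGORICAL[var]
        if col not in table:
            raise SchemaError(f"analysis table lacks column {col!r} for {var!r}")
        out = []
        for level, name in levels.items():
            out.append((name, (table[col] == level).to_numpy(float)))
        return out
    if var in POLY:
        if var not in table:
            raise SchemaError(f"analysis table lacks column {var!r}")
        mat, d = orthogonal_poly(table[var].to_numpy(float), POLY[var])
        return [(f"{var}{_POLY_SUFFIX[j]}", mat[:, j]) for j in range(d)]
    col = CONTINUOUS_ALIASES.get(var, var)
    if col not in table:
        raise SchemaError(f"analysis table lacks column {col!r} for {var!r}")
    return [(var, np.asarray(standardise(table[col].to_numpy(float))))]


@dataclass
class Design:
    """Response, fixed-effects matrix, and random-effects blocks for one fit."""

    y: np.ndarray
    X: pd.DataFrame  # includes the Intercept column
    z_blocks: list  # [(RandomTerm label, indicator/slope matrix n x q, level names)]
    obs_index: tuple  # identifies the observation set for comparability checks
    table: pd.DataFrame


def build_design(table: pd.DataFrame, spec: ModelSpec) -> Design:
    """Construct the design for ``spec`` from an analysis table.

    Applies the model's subset filter, z-scores continuous predictors over
    the filtered table, expands the fixed formula with dummy coding, and
    builds one indicator (or slope) block per random term.
    """
    df = table.query(spec.subset).reset_index(drop=True) if spec.subset else table.reset_index(drop=True)
    if spec.response_col not in df:
        raise SchemaError(f"analysis table lacks response column {spec.response_col!r}")
    if len(df) == 0:
        raise SchemaError(f"model {spec.name}: empty analysis table after subset")
    y = df[spec.response_col].to_numpy(float)

    encodings: dict[str, list] = {}
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(df))}
    for term in expand_formula(spec.fixed):
        for var in term:
            if var not in encodings:
                encodings[var] = _encode_variable(var, df)
        parts = [encodings[var] for var in term]
        stack = [("", np.ones(len(df)))]
        for enc in parts:
            stack = [
                (f"{nm}:{n2}" if nm else n2, v1 * v2)
                for (nm, v1) in stack
                for (n2, v2) in enc
            ]
        for nm, v in stack:
            cols.setdefault(nm, v)
    X = pd.DataFrame(cols)

    z_blocks = []
    for rt in spec.random:
        if rt.group not in df:
            raise SchemaError(f"analysis table lacks grouping column {rt.group!r}")
        levels = sorted(df[rt.group].unique())
        idx = {lv: i for i, lv in enumerate(levels)}
        Z = np.zeros((len(df), len(levels)))
        Z[np.arange(len(df)), [idx[v] for v in df[rt.group]]] = 1.0
        if rt.slope is not None:
            enc = _encode_variable(rt.slope, df)
            if len(enc) != 1:
                raise SchemaError(
                    f"random slope {rt.slope!r} must encode to a single column"
                )
            Z = Z * enc[0][1][:, None]
        z_blocks.append((rt.label, Z, levels))

    if "trial_id" in df:
        obs_index = tuple(df["trial_id"])
    elif {"subject_id", "word"}.issubset(df.columns):
        obs_index = tuple(zip(df["subject_id"], df["word"]))
    elif {"subject_id", "treatment"}.issubset(df.columns):
        obs_index = tuple(zip(df["subject_id"], df["treatment"]))
    else:
        obs_index = tuple(range(len(df)))
    return Design(y=y, X=X, z_blocks=z_blocks, obs_index=obs_index, table=df)
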