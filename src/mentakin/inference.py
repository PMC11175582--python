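"""Fitting, posterior summaries, model comparison and simulation oracles.

Reporting follows the study-style conventions: the posterior mean of a
coefficient (Eμ), its equal-tailed 95% credible interval, and the posterior
probabilities P(Eμ<0) / P(Eμ>0) computed as the fraction of draws on either
side of zero.  Implied slopes in a non-reference condition are summaries of
the draw-wise sum of a base coefficient and its interaction contrast.
Model comparison is PSIS-LOO (expected log pointwise predictive density)
with stacking weights, via arviz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ComparabilityError, MentakinError, SchemaError
from .formulas import Design, ModelSpec, build_design, build_model
from .samplers import FAMILIES, run_ensemble

RHAT_THRESHOLD = 1.01


@dataclass(frozen=True)
class SamplerSettings:
    """Ensemble-sampling budget.

    ``iterations_per_chain`` counts warmup plus retained ensemble steps, so
    the default mirrors a 4-chain, 5,000-iteration, 1,000-warmup run; tests
    and pipelines may pass smaller budgets.
    """

    chains: int = 4
    iterations_per_chain: int = 5000
    warmup: int = 1000
    thin: int = 5
    n_walkers: int | None = None
    loglik_cap: int = 2000

    @property
    def post_steps(self) -> int:
        steps = self.iterations_per_chain - self.warmup
        if steps < 1:
            raise MentakinError("iterations_per_chain must exceed warmup")
        return steps


FAST = SamplerSettings(iterations_per_chain=900, warmup=300, thin=3)


@dataclass(frozen=True)
class CoefficientSummary:
    term: str
    e_mu: float
    cri_lower: float
    cri_upper: float
    p_negative: float
    p_positive: float
    rhat: float | None = None


@dataclass
class PosteriorFit:
    """Posterior draws, diagnostics, and the design the model was fitted to."""

    spec: ModelSpec
    draws: Mapping[str, np.ndarray]  # name -> (chains, draws)
    idata: az.InferenceData
    design: Design
    rhat: Mapping[str, float]
    divergences: int
    chains: int
    iterations_per_chain: int
    warmup: int
    acceptance: float
    seed: int

    @property
    def n_obs(self) -> int:
        return int(self.design.y.size)

    @property
    def terms(self) -> list:
        return list(self.design.X.columns)

    @property
    def max_rhat(self) -> float:
        return float(max(self.rhat.values()))

    @property
    def converged(self) -> bool:
        return self.max_rhat <= RHAT_THRESHOLD and self.divergences == 0


def fit(
    model: ModelSpec | str,
    table: pd.DataFrame,
    seed: int,
    settings: SamplerSettings | None = None,
) -> PosteriorFit:
    """Fit a registered (or ad-hoc) model to an analysis table."""
    spec = build_model(model) if isinstance(model, str) else model
    settings = settings or SamplerSettings()
    design = build_design(table, spec)
    family = FAMILIES[spec.response]
    sampler = family(design, spec)
    result = run_ensemble(
        sampler.log_prob,
        sampler.initial_centre(),
        seed=seed,
        n_warmup=settings.warmup,
        n_steps=settings.post_steps,
        thin=settings.thin,
        n_walkers=settings.n_walkers,
        n_chains=settings.chains,
    )
    fam = sampler.draws(result, seed=seed, loglik_cap=settings.loglik_cap)
    idata = az.from_dict(
        posterior={k: v for k, v in fam.params.items()},
        log_likelihood={"y": fam.log_likelihood},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat_ds = az.rhat(idata)
    rhat = {k: float(rhat_ds[k].values) for k in fam.params}
    return PosteriorFit(
        spec=spec,
        draws=fam.params,
        idata=idata,
        design=design,
        rhat=rhat,
        divergences=0,
        chains=settings.chains,
        iterations_per_chain=settings.iterations_per_chain,
        warmup=settings.warmup,
        acceptance=fam.acceptance,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarise_draws(name: str, flat: np.ndarray, rhat: float | None = None) -> CoefficientSummary:
    """Summary statistics of a raw draw vector (Eμ, CrI, sign probabilities)."""
    lo, hi = np.percentile(flat, [2.5, 97.5])
    return CoefficientSummary(
        term=name,
        e_mu=float(np.mean(flat)),
        cri_lower=float(lo),
        cri_upper=float(hi),
        p_negative=float(np.mean(flat < 0)),
        p_positive=float(np.mean(flat > 0)),
        rhat=rhat,
    )


def summarise(fit_: PosteriorFit, term: str) -> CoefficientSummary:
    """Eμ, equal-tailed 95% CrI and sign probabilities for one term."""
    if term not in fit_.draws:
        raise MentakinError(
            f"term {term!r} not in fit; available: {sorted(fit_.draws)}"
        )
    return summarise_draws(
        term, np.ravel(fit_.draws[term]), fit_.rhat.get(term)
    )


def derived_coefficient(
    fit_: PosteriorFit, base_term: str, contrast_term: str
) -> CoefficientSummary:
    """Summary of the draw-wise sum base + contrast: the implied slope in the
    non-reference condition."""
    for t in (base_term, contrast_term):
        if t not in fit_.draws:
            raise MentakinError(f"term {t!r} not in fit")
    flat = np.ravel(fit_.draws[base_term]) + np.ravel(fit_.draws[contrast_term])
    return summarise_draws(f"{base_term}+{contrast_term}", flat)


def implied_slope(base: float, contrast: float) -> float:
    """Point-estimate slope in the non-reference condition: base + contrast."""
    return float(base) + float(contrast)


def predicted_correct_change(
    slope_per_sd: float, sd_multiple: float = 2.0, trials_per_word: int = 8
) -> float:
    """Trials-correct change implied by a percentage-accuracy slope.

    A slope on the percentage-accuracy-change scale (per SD of the
    predictor), multiplied by the number of predictor SDs considered and by
    the 8 trials a word contributes per session, gives the expected change
    in the number of correctly labelled animations of that word.
    """
    return float(slope_per_sd) * float(sd_multiple) * float(trials_per_word)


def summary_table(fit_: PosteriorFit) -> pd.DataFrame:
    """S-table style layout: term, Eμ, CrI bounds, sign probabilities, Rhat."""
    rows = []
    for name in fit_.draws:
        s = summarise(fit_, name)
        rows.append(
            {
                "term": s.term,
                "e_mu": s.e_mu,
                "cri_lower": s.cri_lower,
                "cri_upper": s.cri_upper,
                "p_negative": s.p_negative,
                "p_positive": s.p_positive,
                "rhat": s.rhat,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model comparison (PSIS-LOO)
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    order: list  # model names, best first
    elpd: Mapping[str, float]
    elpd_diff: Mapping[str, float]  # 0 for the best model, negative below it
    se_diff: Mapping[str, float]
    weights: Mapping[str, float]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.order,
                "elpd_loo": [self.elpd[m] for m in self.order],
                "elpd_diff": [self.elpd_diff[m] for m in self.order],
                "se_diff": [self.se_diff[m] for m in self.order],
                "weight": [self.weights[m] for m in self.order],
            }
        )


def compare(fits: Mapping[str, PosteriorFit]) -> ModelComparison:
    """PSIS-LOO comparison with stacking weights over same-observation fits."""
    if len(fits) < 2:
        raise ComparabilityError("compare needs at least two fits")
    ref = next(iter(fits.values()))
    for name, f in fits.items():
        if f.design.obs_index != ref.design.obs_index:
            raise ComparabilityError(
                f"fit {name!r} was fitted to a different observation set"
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cmp_df = az.compare({k: f.idata for k, f in fits.items()}, ic="loo")
    order = list(cmp_df.index)
    elpd = {m: float(cmp_df.loc[m, "elpd_loo"]) for m in order}
    best = elpd[order[0]]
    return ModelComparison(
        order=order,
        elpd=elpd,
        elpd_diff={m: elpd[m] - best for m in order},
        se_diff={m: float(cmp_df.loc[m, "dse"]) for m in order},
        weights={m: float(cmp_df.loc[m, "weight"]) for m in order},
    )


# ---------------------------------------------------------------------------
# Mixture response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureSummary:
    """Posterior summary of the two accuracy components.

    ``mixing_proportion`` is the posterior-mean weight of the upper
    component; ``split_point`` is where the two weighted component densities
    cross between the means (the empirical boundary between low- and
    high-accuracy trials).  ``degenerate`` flags fits whose weight collapsed
    towards a boundary, where the split is not interpretable.
    """

    component_means: tuple
    component_sds: tuple
    mixing_proportion: float
    split_point: float
    degenerate: bool


def fit_mixture_response(
    table: pd.DataFrame,
    seed: int,
    model: ModelSpec | str = "5",
    settings: SamplerSettings | None = None,
) -> tuple:
    """Fit a 2-component mixture model and summarise its components."""
    spec = build_model(model) if isinstance(model, str) else model
    if spec.response != "gaussian_mixture_2":
        raise MentakinError(f"model {spec.name} does not use the mixture response")
    f = fit(spec, table, seed=seed, settings=settings)
    # Marginal component means: average linear predictor plus intercepts.
    slope_means = {t: float(np.mean(f.draws[t])) for t in f.terms if t != "Intercept"}
    Xs = f.design.X.drop(columns="Intercept")
    eta_bar = float(
        np.mean(Xs.to_numpy() @ np.array([slope_means[c] for c in Xs.columns]))
    ) if len(Xs.columns) else 0.0
    m1 = float(np.mean(f.draws["Intercept"])) + eta_bar
    m2 = float(np.mean(f.draws["mu2"])) + eta_bar
    s1 = float(np.mean(f.draws["sigma1"]))
    s2 = float(np.mean(f.draws["sigma2"]))
    w2 = float(np.mean(f.draws["theta"]))
    degenerate = not (0.05 < w2 < 0.95)

    def crossing(x):
        return (
            np.log1p(-w2)
            + stats.norm.logpdf(x, m1, s1)
            - np.log(w2)
            - stats.norm.logpdf(x, m2, s2)
        )

    split = 0.5 * (m1 + m2)
    if not degenerate and m2 - m1 > 1e-6:
        a, b = m1, m2
        if np.sign(crossing(a)) != np.sign(crossing(b)):
            split = float(optimize.brentq(crossing, a, b))
    return f, MixtureSummary(
        component_means=(m1, m2),
        component_sds=(s1, s2),
        mixing_proportion=w2,
        split_point=split,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Simulation from a model's own structure (recovery / coverage oracles)
# ---------------------------------------------------------------------------

def simulate_from_spec(
    spec: ModelSpec | str,
    table: pd.DataFrame,
    truth: Mapping[str, float],
    seed: int,
) -> pd.DataFrame:
    """Replace the response column by draws from the model's own likelihood.

    ``truth`` maps design-column names (on the z-scored predictor scale) and
    family parameters ("sigma", "nu", random-term sd labels, and for the
    mixture "mu2"/"theta"/"sigma1"/"sigma2") to generating values; missing
    coefficients default to zero.  Returns the (subset-filtered) analysis
    table with the simulated response, suitable for refitting the same spec.
    """
    spec = build_model(spec) if isinstance(spec, str) else spec
    design = build_design(table, spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 13]))
    beta = np.array([float(truth.get(c, 0.0)) for c in design.X.columns])
    eta = design.X.to_numpy(float) @ beta
    for label, Z, levels in design.z_blocks:
        sd = float(truth.get(label, 0.0))
        if sd > 0:
            eta = eta + Z @ rng.normal(0.0, sd, Z.shape[1])
    n = eta.size
    if spec.response == "gaussian":
        y = eta + rng.normal(0.0, float(truth.get("sigma", 1.0)), n)
    elif spec.response == "student_t_truncated":
        sigma = float(truth.get("sigma", 0.2))
        nu = float(truth.get("nu", 20.0))
        lo, hi = spec.truncation
        ua = stats.t.cdf((lo - eta) / sigma, df=nu)
        ub = stats.t.cdf((hi - eta) / sigma, df=nu)
        u = ua + rng.uniform(0.0, 1.0, n) * (ub - ua)
        y = eta + sigma * stats.t.ppf(np.clip(u, 1e-12, 1 - 1e-12), df=nu)
    elif spec.response == "gaussian_mixture_2":
        mu1 = float(truth.get("Intercept", 0.0))
        mu2 = float(truth.get("mu2", mu1 + 1.0))
        w2 = float(truth.get("theta", 0.5))
        s1 = float(truth.get("sigma1", 1.0))
        s2 = float(truth.get("sigma2", 1.0))
        eta_nc = eta - mu1 * (1.0 if "Intercept" in design.X.columns else 0.0)
        comp = rng.random(n) < w2
        y = np.where(
            comp,
            eta_nc + mu2 + rng.normal(0.0, s2, n),
            eta_nc + mu1 + rng.normal(0.0, s1, n),
        )
    else:  # pragma: no cover
        raise MentakinError(f"unknown family {spec.response!r}")
    out = design.table.copy()
    out[spec.response_col] = y
    return out
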