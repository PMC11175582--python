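"""Posterior samplers for the three response families.

All models share the same prior scheme: zero-centred normal priors on
regression coefficients and half-Cauchy priors on every standard deviation
(residual, random-effect, mixture components).  Sampling uses the
affine-invariant stretch-move ensemble (emcee) with a deterministic seeded
state; walkers are partitioned into four groups that play the role of chains
for split-Rhat diagnostics.

Family-specific strategies:

* ``gaussian`` — the joint normal prior over fixed effects and random
  effects is integrated out analytically (Woodbury/determinant-lemma
  identities on precomputed cross-products), so the ensemble only explores
  the 2–4 variance parameters; coefficient draws are then recovered exactly
  from their conditional Gaussian given each variance draw.  This makes the
  hierarchical Gaussian fits fast and immune to funnel geometry.
* ``student_t_truncated`` — direct sampling of coefficients, scale and
  degrees of freedom; the likelihood renormalises the t density to the
  truncation interval.
* ``gaussian_mixture_2`` — shared linear predictor plus two component
  intercepts (ordered via a positive-gap parameterisation), component scales
  and a mixing weight; subject random intercepts are non-centred.
"""

from __future__ import annotations

from dataclasses import dataclass

import emcee
import numpy as np
from scipy import linalg, special, stats

from .errors import MentakinError
from .formulas import Design, ModelSpec

_LOG_2PI = np.log(2.0 * np.pi)


def half_cauchy_log_prior(log_s: np.ndarray, scale: float) -> np.ndarray:
    """Half-Cauchy(0, scale) density of exp(log_s), with the log Jacobian."""
    s = np.exp(log_s)
    return (
        np.log(2.0 / np.pi)
        - np.log(scale)
        - np.log1p((s / scale) ** 2)
        + log_s
    )


@dataclass
class EnsembleResult:
    """Raw ensemble output reshaped into (chains, draws, dim)."""

    theta: np.ndarray
    n_walkers: int
    acceptance: float


def run_ensemble(
    log_prob,
    centre: np.ndarray,
    seed: int,
    n_warmup: int,
    n_steps: int,
    thin: int = 5,
    n_walkers: int | None = None,
    scatter: float = 0.05,
    n_chains: int = 4,
) -> EnsembleResult:
    """Seeded stretch-move sampling around an initial centre.

    Walkers start in a small Gaussian ball around ``centre`` (re-drawn where
    the posterior is not finite), run ``n_warmup`` discarded steps, then
    ``n_steps`` retained steps thinned by ``thin``.  The walker ensemble is
    split into ``n_chains`` groups for diagnostics.
    """
    ndim = centre.size
    if n_walkers is None:
        n_walkers = max(16, 2 * ndim + 2)
    n_walkers = int(np.ceil(n_walkers / n_chains) * n_chains)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 7]))
    p0 = centre[None, :] + scatter * rng.standard_normal((n_walkers, ndim))
    lp = log_prob(p0)
    for _ in range(50):
        bad = ~np.isfinite(lp)
        if not bad.any():
            break
        p0[bad] = centre[None, :] + scatter * rng.standard_normal(
            (int(bad.sum()), ndim)
        )
        lp = log_prob(p0)
    if not np.isfinite(log_prob(p0)).all():
        raise MentakinError("could not initialise walkers at finite posterior density")

    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob, vectorize=True)
    state = emcee.State(
        p0, random_state=np.random.RandomState(int(seed) % 2**32).get_state()
    )
    state = sampler.run_mcmc(state, n_warmup, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, n_steps, progress=False)
    chain = sampler.get_chain(thin=max(int(thin), 1))  # (kept, walkers, dim)
    kept = chain.shape[0]
    # walker-major grouping into chains
    per = n_walkers // n_chains
    theta = (
        chain.transpose(1, 0, 2)
        .reshape(n_chains, per * kept, ndim)
    )
    return EnsembleResult(
        theta=theta,
        n_walkers=n_walkers,
        acceptance=float(np.mean(sampler.acceptance_fraction)),
    )


def _subsample(m: int, cap: int) -> np.ndarray:
    if m <= cap:
        return np.arange(m)
    return np.unique(np.linspace(0, m - 1, cap).round().astype(int))


@dataclass
class FamilyDraws:
    """Named posterior draws plus pointwise log-likelihood."""

    params: dict  # name -> (chains, draws)
    log_likelihood: np.ndarray  # (chains, ll_draws, n_obs)
    acceptance: float


# ---------------------------------------------------------------------------
# Gaussian mixed model, coefficients marginalised
# ---------------------------------------------------------------------------

class MarginalGaussianLMM:
    """Gaussian linear mixed model with all Gaussian layers integrated out.

    With u = (fixed effects, random effects), prior u ~ N(0, D) and
    y | u ~ N(Wu, sigma^2 I), the marginal y ~ N(0, sigma^2 I + W D W')
    is evaluated through the (p+q)-dimensional precision A = D^-1 + W'W /
    sigma^2, so each density evaluation costs one small Cholesky.
    """

    def __init__(self, design: Design, spec: ModelSpec):
        self.design = design
        self.spec = spec
        X = design.X.to_numpy(float)
        self.coef_names = list(design.X.columns)
        self.block_labels = [lbl for lbl, _, _ in design.z_blocks]
        self.W = np.hstack([X] + [Z for _, Z, _ in design.z_blocks]) if design.z_blocks else X
        self.p = X.shape[1]
        self.qs = [Z.shape[1] for _, Z, _ in design.z_blocks]
        self.y = design.y
        self.n = self.y.size
        self.WtW = self.W.T @ self.W
        self.Wty = self.W.T @ self.y
        self.yty = float(self.y @ self.y)
        self.k = len(self.qs)
        self.ndim = self.k + 1
        self.coef_var = spec.priors.coefficient_scale**2
        self.var_scale = spec.priors.variance_scale

    def _prior_var(self, log_taus: np.ndarray) -> np.ndarray:
        parts = [np.full(self.p, self.coef_var)]
        for q, lt in zip(self.qs, log_taus):
            parts.append(np.full(q, np.exp(2.0 * lt)))
        return np.concatenate(parts)

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        out = np.empty(theta.shape[0])
        for i, th in enumerate(theta):
            log_taus, log_sig = th[: self.k], th[self.k]
            if np.any(np.abs(th) > 15):
                out[i] = -np.inf
                continue
            sig2 = np.exp(2.0 * log_sig)
            pv = self._prior_var(log_taus)
            A = self.WtW / sig2 + np.diag(1.0 / pv)
            try:
                L = linalg.cholesky(A, lower=True)
            except linalg.LinAlgError:
                out[i] = -np.inf
                continue
            b = linalg.solve_triangular(L, self.Wty, lower=True) / sig2
            quad = self.yty / sig2 - float(b @ b)
            logdet_v = (
                2.0 * float(np.sum(np.log(np.diag(L))))
                + float(np.sum(np.log(pv)))
                + self.n * 2.0 * log_sig
            )
            ll = -0.5 * (self.n * _LOG_2PI + logdet_v + quad)
            lp = float(
                np.sum(half_cauchy_log_prior(log_taus, self.var_scale))
            ) + float(half_cauchy_log_prior(np.array(log_sig), self.var_scale))
            out[i] = ll + lp
        return out

    def initial_centre(self) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(self.W[:, : self.p], self.y, rcond=None)
        resid_sd = float(np.std(self.y - self.W[:, : self.p] @ beta)) or 1.0
        centre = np.full(self.ndim, np.log(max(resid_sd / 2.0, 1e-3)))
        centre[-1] = np.log(resid_sd)
        return centre

    def draws(
        self, result: EnsembleResult, seed: int, loglik_cap: int = 2000
    ) -> FamilyDraws:
        """Exact conditional coefficient draws given each variance draw."""
        chains, m, _ = result.theta.shape
        theta = result.theta.reshape(chains * m, self.ndim)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 11]))
        d = self.p + sum(self.qs)
        u = np.empty((chains * m, d))
        for i, th in enumerate(theta):
            log_taus, log_sig = th[: self.k], th[self.k]
            sig2 = np.exp(2.0 * log_sig)
            pv = self._prior_var(log_taus)
            A = self.WtW / sig2 + np.diag(1.0 / pv)
            L = linalg.cholesky(A, lower=True)
            mean = linalg.cho_solve((L, True), self.Wty / sig2)
            z = rng.standard_normal(d)
            u[i] = mean + linalg.solve_triangular(L.T, z, lower=False)

        params = {
            name: u[:, j].reshape(chains, m) for j, name in enumerate(self.coef_names)
        }
        for j, lbl in enumerate(self.block_labels):
            params[lbl] = np.exp(theta[:, j]).reshape(chains, m)
        params["sigma"] = np.exp(theta[:, self.k]).reshape(chains, m)

        sel = _subsample(m, max(loglik_cap // chains, 1))
        sigma_flat = np.exp(theta[:, self.k]).reshape(chains, m)[:, sel]
        u_sel = u.reshape(chains, m, d)[:, sel, :]
        mu = np.einsum("cmd,nd->cmn", u_sel, self.W)
        resid = self.y[None, None, :] - mu
        ll = (
            -0.5 * _LOG_2PI
            - np.log(sigma_flat)[:, :, None]
            - 0.5 * (resid / sigma_flat[:, :, None]) ** 2
        )
        return FamilyDraws(params=params, log_likelihood=ll, acceptance=result.acceptance)


# ---------------------------------------------------------------------------
# Truncated Student-t regression
# ---------------------------------------------------------------------------

class TruncatedTRegression:
    """Student-t linear model with the response truncated to a fixed interval.

    Parameter vector: regression coefficients, log scale, log degrees of
    freedom (gamma(2, 0.1) prior on nu).
    """

    NU_SHAPE, NU_RATE = 2.0, 0.1

    def __init__(self, design: Design, spec: ModelSpec):
        if design.z_blocks:
            raise MentakinError("truncated-t family supports fixed effects only")
        self.design = design
        self.spec = spec
        self.X = design.X.to_numpy(float)
        self.coef_names = list(design.X.columns)
        self.y = design.y
        self.n = self.y.size
        self.p = self.X.shape[1]
        self.lower, self.upper = spec.truncation
        self.ndim = self.p + 2
        self.coef_scale = spec.priors.coefficient_scale
        self.var_scale = spec.priors.variance_scale

    def _loglik_matrix(self, beta, log_sig, log_nu):
        sigma = np.exp(log_sig)[:, None]
        nu = np.exp(log_nu)[:, None]
        mu = beta @ self.X.T
        z = (self.y[None, :] - mu) / sigma
        ll = stats.t.logpdf(z, df=nu) - np.log(sigma)
        za = (self.lower - mu) / sigma
        zb = (self.upper - mu) / sigma
        norm = stats.t.cdf(zb, df=nu) - stats.t.cdf(za, df=nu)
        return ll - np.log(np.clip(norm, 1e-300, None))

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        beta = theta[:, : self.p]
        log_sig = theta[:, self.p]
        log_nu = theta[:, self.p + 1]
        bad = (np.abs(theta) > 15).any(axis=1) | (log_nu > np.log(500))
        ll = np.where(
            bad[:, None], 0.0, self._loglik_matrix(beta, log_sig, log_nu)
        ).sum(axis=1)
        nu = np.exp(log_nu)
        lp = (
            -0.5 * np.sum((beta / self.coef_scale) ** 2, axis=1)
            + half_cauchy_log_prior(log_sig, self.var_scale)
            + self.NU_SHAPE * np.log(self.NU_RATE)
            - special.gammaln(self.NU_SHAPE)
            + self.NU_SHAPE * log_nu
            - self.NU_RATE * nu
        )
        return np.where(bad, -np.inf, ll + lp)

    def initial_centre(self) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid_sd = float(np.std(self.y - self.X @ beta)) or 0.1
        return np.concatenate([beta, [np.log(resid_sd), np.log(20.0)]])

    def draws(
        self, result: EnsembleResult, seed: int, loglik_cap: int = 2000
    ) -> FamilyDraws:
        chains, m, _ = result.theta.shape
        theta = result.theta
        params = {
            name: theta[:, :, j] for j, name in enumerate(self.coef_names)
        }
        params["sigma"] = np.exp(theta[:, :, self.p])
        params["nu"] = np.exp(theta[:, :, self.p + 1])
        sel = _subsample(m, max(loglik_cap // chains, 1))
        flat = theta[:, sel, :].reshape(chains * sel.size, self.ndim)
        ll = self._loglik_matrix(
            flat[:, : self.p], flat[:, self.p], flat[:, self.p + 1]
        ).reshape(chains, sel.size, self.n)
        return FamilyDraws(params=params, log_likelihood=ll, acceptance=result.acceptance)


# ---------------------------------------------------------------------------
# Two-component Gaussian mixture regression
# ---------------------------------------------------------------------------

class MixtureRegression:
    """Mixture of two Gaussians around a shared linear predictor.

    The two components share every slope and the (optional, non-centred)
    subject random intercept but have their own intercepts and scales; the
    upper intercept is the lower one plus a strictly positive gap, which
    keeps the components ordered and identified.  ``theta`` is the weight of
    the upper component.
    """

    def __init__(self, design: Design, spec: ModelSpec):
        if len(design.z_blocks) > 1:
            raise MentakinError("mixture family supports one random-intercept block")
        self.design = design
        self.spec = spec
        X = design.X.to_numpy(float)
        self.slope_names = list(design.X.columns)[1:]
        self.Xs = X[:, 1:]
        self.y = design.y
        self.n = self.y.size
        self.p = self.Xs.shape[1]
        if design.z_blocks:
            _, Z, levels = design.z_blocks[0]
            self.group_idx = np.argmax(Z, axis=1)
            self.q = Z.shape[1]
            self.block_label = design.z_blocks[0][0]
        else:
            self.group_idx = None
            self.q = 0
            self.block_label = None
        # layout: slopes(p), mu1, log_gap, log_sig1, log_sig2, logit_theta,
        #         [b_raw(q), log_tau]
        self.ndim = self.p + 5 + (self.q + 1 if self.q else 0)
        self.coef_scale = spec.priors.coefficient_scale
        self.var_scale = spec.priors.variance_scale

    def _unpack(self, theta):
        p = self.p
        beta = theta[:, :p]
        mu1 = theta[:, p]
        gap = np.exp(theta[:, p + 1])
        sig1 = np.exp(theta[:, p + 2])
        sig2 = np.exp(theta[:, p + 3])
        w2 = special.expit(theta[:, p + 4])
        if self.q:
            b_raw = theta[:, p + 5 : p + 5 + self.q]
            tau = np.exp(theta[:, -1])
        else:
            b_raw, tau = None, None
        return beta, mu1, gap, sig1, sig2, w2, b_raw, tau

    def _loglik_matrix(self, theta):
        beta, mu1, gap, sig1, sig2, w2, b_raw, tau = self._unpack(theta)
        eta = beta @ self.Xs.T if self.p else np.zeros((theta.shape[0], self.n))
        if self.q:
            eta = eta + (b_raw * tau[:, None])[:, self.group_idx]
        r1 = self.y[None, :] - eta - mu1[:, None]
        r2 = r1 - gap[:, None]
        l1 = (
            np.log1p(-w2)[:, None]
            - np.log(sig1)[:, None]
            - 0.5 * _LOG_2PI
            - 0.5 * (r1 / sig1[:, None]) ** 2
        )
        l2 = (
            np.log(w2)[:, None]
            - np.log(sig2)[:, None]
            - 0.5 * _LOG_2PI
            - 0.5 * (r2 / sig2[:, None]) ** 2
        )
        return np.logaddexp(l1, l2)

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        bad = (np.abs(theta) > 18).any(axis=1)
        safe = np.where(bad[:, None], 0.0, theta)
        ll = self._loglik_matrix(safe).sum(axis=1)
        beta, mu1, gap, sig1, sig2, w2, b_raw, tau = self._unpack(safe)
        p = self.p
        lp = (
            -0.5 * np.sum((beta / self.coef_scale) ** 2, axis=1)
            - 0.5 * (mu1 / self.coef_scale) ** 2
            # half-normal(5) on the gap, with log Jacobian
            - 0.5 * (gap / 5.0) ** 2
            + theta[:, p + 1]
            + half_cauchy_log_prior(theta[:, p + 2], self.var_scale)
            + half_cauchy_log_prior(theta[:, p + 3], self.var_scale)
            # uniform mixing weight via logit Jacobian
            + np.log(w2)
            + np.log1p(-w2)
        )
        if self.q:
            lp = (
                lp
                - 0.5 * np.sum(b_raw**2, axis=1)
                + half_cauchy_log_prior(theta[:, -1], self.var_scale)
            )
        return np.where(bad, -np.inf, ll + lp)

    def initial_centre(self) -> np.ndarray:
        if self.p:
            beta, *_ = np.linalg.lstsq(self.Xs, self.y - self.y.mean(), rcond=None)
            resid = self.y - self.Xs @ beta
        else:
            beta = np.zeros(0)
            resid = self.y.copy()
        med = np.median(resid)
        lo, hi = resid[resid <= med], resid[resid > med]
        mu1 = float(lo.mean())
        gap = max(float(hi.mean() - lo.mean()), 0.5)
        s1 = max(float(lo.std()), 0.2)
        s2 = max(float(hi.std()), 0.2)
        centre = np.concatenate(
            [
                beta,
                [mu1, np.log(gap), np.log(s1), np.log(s2), 0.0],
            ]
        )
        if self.q:
            centre = np.concatenate([centre, np.zeros(self.q), [np.log(0.3)]])
        return centre

    def draws(
        self, result: EnsembleResult, seed: int, loglik_cap: int = 2000
    ) -> FamilyDraws:
        chains, m, _ = result.theta.shape
        theta = result.theta
        p = self.p
        params = {"Intercept": theta[:, :, p]}
        for j, name in enumerate(self.slope_names):
            params[name] = theta[:, :, j]
        params["mu2"] = theta[:, :, p] + np.exp(theta[:, :, p + 1])
        params["sigma1"] = np.exp(theta[:, :, p + 2])
        params["sigma2"] = np.exp(theta[:, :, p + 3])
        params["theta"] = special.expit(theta[:, :, p + 4])
        if self.q:
            params[self.block_label] = np.exp(theta[:, :, -1])
        sel = _subsample(m, max(loglik_cap // chains, 1))
        flat = theta[:, sel, :].reshape(chains * sel.size, self.ndim)
        ll = self._loglik_matrix(flat).reshape(chains, sel.size, self.n)
        return FamilyDraws(params=params, log_likelihood=ll, acceptance=result.acceptance)


FAMILIES = {
    "gaussian": MarginalGaussianLMM,
    "student_t_truncated": TruncatedTRegression,
    "gaussian_mixture_2": MixtureRegression,
}
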