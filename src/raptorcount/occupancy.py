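"""Bayesian hierarchical multi-species occupancy model.

The model treats each species k as a random member of the surveyed
community.  True occurrence at site i is a latent Bernoulli variable

    z_ik ~ Bernoulli(psi_ik),
    logit(psi_ik) = a_k + sum_c beta_ck * x_ic,

where x_i are standardized distances to the anthropogenic feature classes.
Detection on replicate j is conditional on occurrence,

    y_ijk | z_ik ~ Bernoulli(p_k * z_ik),    logit(p_k) = b_k,

with a constant, species-specific detection probability.  Species-level
parameters are draws from community hyper-distributions: the occupancy and
detection intercepts (a_k, b_k) are jointly bivariate normal with
correlation rho (abundant species tend to be both widespread and easy to
detect), and each slope beta_ck ~ Normal(mu_beta_c, sigma_beta_c).

Site species richness is never modelled directly; it is the derived
quantity N_i = sum_k z_ik computed from posterior draws of the latent
occurrence matrix.  Community-level effects of each feature class on
richness are read off the hyper-means mu_beta_c: because covariates are
distances, a negative hyper-mean says richness increases with proximity.

Inference is Metropolis-within-Gibbs: the latent z are updated by exact
Gibbs draws from their full conditional, all continuous parameters by
adaptive random-walk Metropolis with the step sizes frozen after burn-in
so the post-burn-in kernel satisfies detailed balance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm as _norm

from .data import DetectionHistory, SiteCovariates, FEATURE_CLASSES


class ParameterError(ValueError):
    """A parameter is outside its legal domain."""


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class CommunityHyperParams:
    """Community-level hyper-parameters governing species-level effects.

    mu_a / sigma_a : hyper-mean and SD of occupancy intercepts (logit scale)
    mu_b / sigma_b : hyper-mean and SD of detection intercepts (logit scale)
    rho            : correlation between a species' occupancy and detection
                     intercepts, in [-1, 1]
    mu_beta / sigma_beta : per-covariate hyper-means and SDs of the slopes
    """

    mu_a: float
    sigma_a: float
    mu_b: float
    sigma_b: float
    rho: float
    mu_beta: np.ndarray
    sigma_beta: np.ndarray

    def __post_init__(self) -> None:
        self.mu_beta = np.atleast_1d(np.asarray(self.mu_beta, dtype=float))
        self.sigma_beta = np.atleast_1d(np.asarray(self.sigma_beta, dtype=float))
        if self.mu_beta.shape != self.sigma_beta.shape:
            raise ParameterError("mu_beta and sigma_beta must have the same length")
        if self.sigma_a < 0 or self.sigma_b < 0 or np.any(self.sigma_beta < 0):
            raise ParameterError("hyper standard deviations must be nonnegative")
        if not -1.0 <= self.rho <= 1.0:
            raise ParameterError("rho must lie in [-1, 1]")

    @property
    def n_covariates(self) -> int:
        return self.mu_beta.shape[0]


@dataclass
class SpeciesEffects:
    """Realized species-level parameters: a (K,), b (K,), beta (C, K)."""

    a: np.ndarray
    b: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))
                and np.all(np.isfinite(self.beta))):
            raise ParameterError("species effects must be finite")
        if self.beta.shape[1] != self.a.shape[0] or self.b.shape != self.a.shape:
            raise ParameterError("inconsistent species-effect shapes")


@dataclass
class OccupancyState:
    """One point in the sampler's state space."""

    z: np.ndarray  # (S, K) in {0, 1}
    effects: SpeciesEffects
    hyper: CommunityHyperParams


@dataclass
class PriorConfig:
    """Weakly informative hyper-priors: Normal(0, mean_sd) on hyper-means,
    Uniform(0, sigma_upper) on hyper-SDs, Uniform(-1, 1) on rho."""

    mean_sd: float = 10.0
    sigma_upper: float = 10.0


@dataclass
class MCMCConfig:
    """Sampler settings.  Defaults are a desk-scale configuration (3 chains
    of 20,000 iterations, first half burn-in, thinned to 2,000 kept draws
    per chain); heavier schedules are available by raising n_iter."""

    n_chains: int = 3
    n_iter: int = 20_000
    burn_in: int | None = None  # defaults to n_iter // 2
    n_keep: int = 2_000  # kept draws per chain after thinning
    seed: int = 0
    target_accept: float = 0.35
    adapt_interval: int = 50
    fix_hypers: CommunityHyperParams | None = None
    priors: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self) -> None:
        if self.burn_in is None:
            self.burn_in = self.n_iter // 2
        if self.n_chains < 2:
            raise ParameterError("at least 2 chains are required for Rhat")


@dataclass
class PosteriorChains:
    """Post-burn-in MCMC draws from all chains plus metadata.

    hyper_draws   : name -> (n_chains, n_kept) arrays
    species_draws : name ('a', 'b', 'beta_<c>') -> (n_chains, n_kept, K)
    z_draws       : (n_chains, n_kept, S, K) uint8 latent occurrence draws
    """

    hyper_draws: dict[str, np.ndarray]
    species_draws: dict[str, np.ndarray]
    z_draws: np.ndarray
    site_ids: list[str]
    species_names: list[str]
    feature_names: tuple[str, ...]
    config: MCMCConfig
    acceptance_rates: dict[str, float]

    @property
    def n_chains(self) -> int:
        return self.z_draws.shape[0]

    @property
    def n_kept(self) -> int:
        return self.z_draws.shape[1]

    def parameter(self, name: str) -> np.ndarray:
        """(n_chains, n_kept) draws for one monitored scalar parameter."""
        if name in self.hyper_draws:
            return self.hyper_draws[name]
        raise KeyError(name)

    def rhat_table(self) -> pd.DataFrame:
        """Gelman-Rubin Rhat for every monitored hyper-parameter."""
        rows = [
            {"parameter": name, "rhat": gelman_rubin(draws)}
            for name, draws in self.hyper_draws.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class RichnessPosterior:
    """Posterior of derived per-site species richness N_i = sum_k z_ik."""

    draws: np.ndarray  # (n_draws_total, S)
    mean: np.ndarray
    lower: np.ndarray  # 2.5%
    upper: np.ndarray  # 97.5%
    site_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": self.site_ids,
                "richness_mean": self.mean,
                "richness_2.5%": self.lower,
                "richness_97.5%": self.upper,
            }
        )


# ---------------------------------------------------------------------------
# Elementary model functions
# ---------------------------------------------------------------------------


def _log_sigmoid(t: np.ndarray) -> np.ndarray:
    # log(1 / (1 + e^-t)), stable for large |t|
    return -np.logaddexp(0.0, -t)


def occupancy_probability(intercept, beta, x) -> np.ndarray:
    """Occupancy probability from the logit-linear model.

    psi = inv-logit(intercept + beta . x).  Broadcasts over arrays; x and
    beta must have matching trailing length.
    """
    intercept = np.asarray(intercept, dtype=float)
    beta = np.asarray(beta, dtype=float)
    x = np.asarray(x, dtype=float)
    eta = intercept + np.sum(beta * x, axis=-1)
    if not np.all(np.isfinite(eta)):
        raise ParameterError("non-finite linear predictor")
    return expit(eta)


def z_full_conditional(psi: float, p: float, n_surveys: int, n_detections: int) -> float:
    """P(z = 1 | data) for one site-species cell.

    With at least one detection occupancy is certain.  With none, Bayes'
    rule over the J surveyed replicates gives
    psi (1-p)^J / (psi (1-p)^J + 1 - psi).
    """
    if not (0.0 <= psi <= 1.0 and 0.0 <= p <= 1.0):
        raise ParameterError("psi and p must be probabilities")
    if n_detections > n_surveys or n_detections < 0:
        raise ParameterError("n_detections must lie in [0, n_surveys]")
    if n_detections > 0:
        return 1.0
    w1 = psi * (1.0 - p) ** n_surveys
    return w1 / (w1 + (1.0 - psi))


def _bvn_logpdf(a, b, mu_a, mu_b, sigma_a, sigma_b, rho):
    """Bivariate normal log-density of the intercept pairs (a_k, b_k).

    Degenerate cases: if one SD is zero that margin is a point mass (its
    contribution is dropped and the other margin is an independent normal);
    |rho| = 1 with positive SDs is rejected as improper for sampling.
    """
    if sigma_a == 0.0 and sigma_b == 0.0:
        return np.zeros(np.broadcast(a, b).shape)
    if sigma_a == 0.0:
        return _norm.logpdf(b, mu_b, sigma_b)
    if sigma_b == 0.0:
        return _norm.logpdf(a, mu_a, sigma_a)
    if abs(rho) >= 1.0:
        return np.full(np.broadcast(a, b).shape, -np.inf)
    za = (a - mu_a) / sigma_a
    zb = (b - mu_b) / sigma_b
    om = 1.0 - rho**2
    return (
        -np.log(2.0 * np.pi * sigma_a * sigma_b * np.sqrt(om))
        - (za**2 - 2.0 * rho * za * zb + zb**2) / (2.0 * om)
    )


def log_joint(
    state: OccupancyState,
    data: DetectionHistory,
    X: np.ndarray,
    priors: PriorConfig | None = PriorConfig(),
) -> float:
    """Log of the full joint density of data, latent states and parameters.

    Terms: Bernoulli observation likelihood over surveyed replicates,
    Bernoulli latent-occurrence probability, species-effect densities under
    the community hyper-distributions, and (unless ``priors`` is None,
    meaning hyper-parameters are held fixed) the hyper-prior densities.
    Returns -inf for states inconsistent with the data (z = 0 where the
    species was detected).
    """
    from scipy.stats import norm

    X = np.asarray(X, dtype=float)
    z = np.asarray(state.z)
    eff = state.effects
    hyp = state.hyper
    D = data.detections_per_site()  # (S, K)
    J = data.surveys_per_site  # (S,)

    if np.any((z == 0) & (D > 0)):
        return -np.inf

    eta = eff.a[None, :] + X @ eff.beta  # (S, K)
    log_psi = _log_sigmoid(eta)
    log_1mpsi = _log_sigmoid(-eta)
    lp_z = float(np.sum(z * log_psi + (1 - z) * log_1mpsi))

    log_p = _log_sigmoid(eff.b)  # (K,)
    log_1mp = _log_sigmoid(-eff.b)
    lp_obs = float(np.sum(z * (D * log_p[None, :] + (J[:, None] - D) * log_1mp[None, :])))

    lp_eff = float(
        np.sum(_bvn_logpdf(eff.a, eff.b, hyp.mu_a, hyp.mu_b, hyp.sigma_a, hyp.sigma_b, hyp.rho))
    )
    for c in range(hyp.n_covariates):
        if hyp.sigma_beta[c] == 0.0:
            continue  # point mass, zero contribution
        lp_eff += float(np.sum(norm.logpdf(eff.beta[c], hyp.mu_beta[c], hyp.sigma_beta[c])))

    lp_hyper = 0.0
    if priors is not None:
        means = [hyp.mu_a, hyp.mu_b, *hyp.mu_beta]
        lp_hyper += float(np.sum(norm.logpdf(means, 0.0, priors.mean_sd)))
        sigmas = np.array([hyp.sigma_a, hyp.sigma_b, *hyp.sigma_beta])
        if np.any(sigmas < 0) or np.any(sigmas > priors.sigma_upper):
            return -np.inf
        lp_hyper += -len(sigmas) * np.log(priors.sigma_upper)
        if not -1.0 <= hyp.rho <= 1.0:
            return -np.inf
        lp_hyper += -np.log(2.0)

    return lp_obs + lp_z + lp_eff + lp_hyper


# ---------------------------------------------------------------------------
# Metropolis-within-Gibbs sampler
#
# All chains are advanced together: every state array carries a leading
# chain axis, so one numpy operation serves M chains at once.  Chains never
# interact — proposals, acceptances and adaptation are per chain — they
# merely share vectorized arithmetic.
# ---------------------------------------------------------------------------


def _bvn_logpdf_vec(a, b, mu_a, mu_b, sigma_a, sigma_b, rho):
    """Bivariate-normal log-density with per-chain parameters.

    a, b are (M, K); the parameters are (M, 1) columns with sigmas > 0 and
    |rho| < 1 (the sampler rejects proposals outside those supports before
    calling this)."""
    za = (a - mu_a) / sigma_a
    zb = (b - mu_b) / sigma_b
    om = 1.0 - rho**2
    return (
        -np.log(2.0 * np.pi * sigma_a * sigma_b * np.sqrt(om))
        - (za**2 - 2.0 * rho * za * zb + zb**2) / (2.0 * om)
    )


class _VectorChains:
    """Sampler state for all chains at once.

    Shapes: a, b, zll, dll (M, K); beta (M, C, K); z, eta (M, S, K);
    hyper-parameters (M,) or (M, C).  The linear predictor eta and the
    per-species log-likelihood pieces zll (occurrence) and dll (detection)
    are cached and updated incrementally.
    """

    def __init__(self, rng, X, D, J, config: MCMCConfig, n_species: int):
        self.rng = rng
        self.X = X
        self.D = D[None, :, :]  # (1, S, K) detections per site/species
        self.J = J[None, :, None].astype(float)  # (1, S, 1) surveys per site
        self.M = config.n_chains
        self.S, self.C = X.shape[0], X.shape[1]
        self.K = n_species
        self.cfg = config
        M, C, K = self.M, self.C, self.K

        fix = config.fix_hypers
        self.fixed = fix is not None
        if self.fixed:
            ones = np.ones(M)
            self.mu_a = ones * fix.mu_a
            self.sigma_a = ones * fix.sigma_a
            self.mu_b = ones * fix.mu_b
            self.sigma_b = ones * fix.sigma_b
            self.rho = ones * fix.rho
            self.mu_beta = np.tile(fix.mu_beta, (M, 1))
            self.sigma_beta = np.tile(fix.sigma_beta, (M, 1))
        else:
            self.mu_a = rng.normal(0, 1, M)
            self.sigma_a = rng.uniform(0.5, 2.0, M)
            self.mu_b = rng.normal(0, 1, M)
            self.sigma_b = rng.uniform(0.5, 2.0, M)
            self.rho = rng.uniform(-0.5, 0.5, M)
            self.mu_beta = rng.normal(0, 1, (M, C))
            self.sigma_beta = rng.uniform(0.5, 2.0, (M, C))

        self.a = self.mu_a[:, None] + self.sigma_a[:, None] * rng.standard_normal((M, K))
        self.b = self.mu_b[:, None] + self.sigma_b[:, None] * rng.standard_normal((M, K))
        self.beta = self.mu_beta[:, :, None] + self.sigma_beta[:, :, None] * (
            rng.standard_normal((M, C, K))
        )
        self.z = np.where(
            self.D > 0, 1, (rng.random((M, self.S, K)) < 0.5).astype(np.int8)
        )
        self.eta = self._full_eta()
        self.zll = self._z_loglik(self.eta)
        self.dll = self._det_loglik(self.b)

        # random-walk step sizes, one per chain per block, adapted during
        # burn-in only (frozen afterwards to preserve detailed balance)
        self.steps: dict[str, np.ndarray] = {
            "a": np.full(M, 0.5), "b": np.full(M, 0.5), "beta": np.full((M, C), 0.5),
            "mu_a": np.full(M, 0.5), "sigma_a": np.full(M, 0.5),
            "mu_b": np.full(M, 0.5), "sigma_b": np.full(M, 0.5),
            "rho": np.full(M, 0.3),
            "mu_beta": np.full((M, C), 0.5), "sigma_beta": np.full((M, C), 0.5),
            "group_a": np.full(M, 0.3), "group_b": np.full(M, 0.3),
            "group_beta": np.full((M, C), 0.3),
        }
        self.acc = {k: np.zeros_like(v) for k, v in self.steps.items()}
        self.tries = {k: 0.0 for k in self.steps}
        self.acc_total = {k: np.zeros_like(v) for k, v in self.steps.items()}
        self.tries_total = {k: 0.0 for k in self.steps}

    # -- cached likelihood pieces ---------------------------------------

    def _full_eta(self):
        # (M, S, K) = a + X @ beta per chain
        return self.a[:, None, :] + np.einsum("sc,mck->msk", self.X, self.beta)

    def _z_loglik(self, eta):
        """(M, K): per-species occurrence log-likelihood, using
        z log(psi) + (1-z) log(1-psi) = z*eta + log sigmoid(-eta)."""
        return np.sum(self.z * eta + _log_sigmoid(-eta), axis=1)

    def _det_loglik(self, b):
        """(M, K): detection log-likelihood at detection intercepts b."""
        log_p = _log_sigmoid(b)[:, None, :]
        log_1mp = _log_sigmoid(-b)[:, None, :]
        return np.sum(self.z * (self.D * log_p + (self.J - self.D) * log_1mp), axis=1)

    def _intercept_prior(self, a, b):
        """(M, K) log-density of the intercept pairs under the current
        bivariate hyper-distribution (degenerate margins handled)."""
        sa = self.sigma_a[:, None]
        sb = self.sigma_b[:, None]
        if self.fixed and (np.all(sa == 0.0) or np.all(sb == 0.0)):
            lp = np.zeros((self.M, self.K))
            if np.any(sa > 0):
                lp += -0.5 * ((a - self.mu_a[:, None]) / sa) ** 2 - np.log(sa)
            if np.any(sb > 0):
                lp += -0.5 * ((b - self.mu_b[:, None]) / sb) ** 2 - np.log(sb)
            return lp
        return _bvn_logpdf_vec(
            a, b, self.mu_a[:, None], self.mu_b[:, None], sa, sb, self.rho[:, None]
        )

    def _track(self, key, acc_rate):
        self.acc[key] += acc_rate
        self.tries[key] += 1.0
        self.acc_total[key] += acc_rate
        self.tries_total[key] += 1.0

    # -- update blocks ---------------------------------------------------

    def update_z(self):
        """Exact Gibbs draw of the latent occurrence tensor."""
        log_p1m = _log_sigmoid(-self.b)[:, None, :]
        # log-odds of occupancy given J all-zero surveys: eta + J log(1-p)
        prob = expit(self.eta + self.J * log_p1m)
        u = self.rng.random(self.z.shape)
        self.z = np.where(self.D > 0, 1, (u < prob).astype(np.int8))
        self.zll = self._z_loglik(self.eta)
        self.dll = self._det_loglik(self.b)

    def update_a(self):
        if self.fixed and np.all(self.sigma_a == 0.0):
            return  # intercepts pinned to the fixed hyper-mean
        prop = self.a + self.steps["a"][:, None] * self.rng.standard_normal((self.M, self.K))
        eta_prop = self.eta + (prop - self.a)[:, None, :]
        zll_prop = self._z_loglik(eta_prop)
        delta = (
            zll_prop - self.zll
            + self._intercept_prior(prop, self.b) - self._intercept_prior(self.a, self.b)
        )
        acc = np.log(self.rng.random(delta.shape)) < delta
        self._track("a", acc.mean(axis=1))
        self.a = np.where(acc, prop, self.a)
        self.eta = np.where(acc[:, None, :], eta_prop, self.eta)
        self.zll = np.where(acc, zll_prop, self.zll)

    def update_b(self):
        if self.fixed and np.all(self.sigma_b == 0.0):
            return
        prop = self.b + self.steps["b"][:, None] * self.rng.standard_normal((self.M, self.K))
        dll_prop = self._det_loglik(prop)
        delta = (
            dll_prop - self.dll
            + self._intercept_prior(self.a, prop) - self._intercept_prior(self.a, self.b)
        )
        acc = np.log(self.rng.random(delta.shape)) < delta
        self._track("b", acc.mean(axis=1))
        self.b = np.where(acc, prop, self.b)
        self.dll = np.where(acc, dll_prop, self.dll)

    def update_beta(self):
        for c in range(self.C):
            if self.fixed and np.all(self.sigma_beta[:, c] == 0.0):
                continue  # slopes pinned to the fixed hyper-mean
            cur = self.beta[:, c, :]
            prop = cur + self.steps["beta"][:, c, None] * self.rng.standard_normal(
                (self.M, self.K)
            )
            eta_prop = self.eta + self.X[None, :, c, None] * (prop - cur)[:, None, :]
            zll_prop = self._z_loglik(eta_prop)
            mu = self.mu_beta[:, c, None]
            sd = np.maximum(self.sigma_beta[:, c, None], 1e-12)
            delta = zll_prop - self.zll - 0.5 * ((prop - mu) ** 2 - (cur - mu) ** 2) / sd**2
            acc = np.log(self.rng.random(delta.shape)) < delta
            rate = np.zeros((self.M, self.C))
            rate[:, c] = acc.mean(axis=1)
            self.acc["beta"] += rate
            self.acc_total["beta"] += rate
            self.beta[:, c, :] = np.where(acc, prop, cur)
            self.eta = np.where(acc[:, None, :], eta_prop, self.eta)
            self.zll = np.where(acc, zll_prop, self.zll)
        self.tries["beta"] += 1.0
        self.tries_total["beta"] += 1.0

    # -- hyper-parameter blocks -----------------------------------------

    def _intercept_hyper_loglik(self, mu_a, sigma_a, mu_b, sigma_b, rho):
        """(M,) log-density of all intercept pairs + hyper-mean priors."""
        pr = self.cfg.priors
        ok = (
            (sigma_a > 0) & (sigma_a <= pr.sigma_upper)
            & (sigma_b > 0) & (sigma_b <= pr.sigma_upper)
            & (np.abs(rho) < 1.0)
        )
        sa = np.where(ok, sigma_a, 1.0)[:, None]
        sb = np.where(ok, sigma_b, 1.0)[:, None]
        r = np.where(ok, rho, 0.0)[:, None]
        ll = _bvn_logpdf_vec(self.a, self.b, mu_a[:, None], mu_b[:, None], sa, sb, r).sum(axis=1)
        ll += -0.5 * (mu_a**2 + mu_b**2) / pr.mean_sd**2
        return np.where(ok, ll, -np.inf)

    def update_hypers(self):
        if self.fixed:
            return
        keys = ("mu_a", "sigma_a", "mu_b", "sigma_b", "rho")
        vals = {k: getattr(self, k) for k in keys}
        cur_ll = self._intercept_hyper_loglik(**vals)
        for key in keys:
            prop = vals[key] + self.steps[key] * self.rng.standard_normal(self.M)
            prop_vals = dict(vals)
            prop_vals[key] = prop
            prop_ll = self._intercept_hyper_loglik(**prop_vals)
            acc = np.log(self.rng.random(self.M)) < prop_ll - cur_ll
            self._track(key, acc.astype(float))
            vals[key] = np.where(acc, prop, vals[key])
            cur_ll = np.where(acc, prop_ll, cur_ll)
            setattr(self, key, vals[key])

        pr = self.cfg.priors
        # slope hyper-means, vectorized over chains and covariates
        ss_cur = np.sum((self.beta - self.mu_beta[:, :, None]) ** 2, axis=2)  # (M, C)
        prop_mu = self.mu_beta + self.steps["mu_beta"] * self.rng.standard_normal(
            (self.M, self.C)
        )
        ss_prop = np.sum((self.beta - prop_mu[:, :, None]) ** 2, axis=2)
        delta = (
            -0.5 * ss_prop / self.sigma_beta**2 - 0.5 * prop_mu**2 / pr.mean_sd**2
            + 0.5 * ss_cur / self.sigma_beta**2 + 0.5 * self.mu_beta**2 / pr.mean_sd**2
        )
        acc = np.log(self.rng.random(delta.shape)) < delta
        self._track("mu_beta", acc.astype(float))
        self.mu_beta = np.where(acc, prop_mu, self.mu_beta)

        # slope hyper-SDs
        ss_cur = np.sum((self.beta - self.mu_beta[:, :, None]) ** 2, axis=2)
        prop_sd = self.sigma_beta + self.steps["sigma_beta"] * self.rng.standard_normal(
            (self.M, self.C)
        )
        ok = (prop_sd > 0) & (prop_sd <= pr.sigma_upper)
        safe = np.where(ok, prop_sd, 1.0)
        delta = np.where(
            ok,
            -self.K * np.log(safe) - 0.5 * ss_cur / safe**2
            + self.K * np.log(self.sigma_beta) + 0.5 * ss_cur / self.sigma_beta**2,
            -np.inf,
        )
        acc = np.log(self.rng.random(delta.shape)) < delta
        self._track("sigma_beta", acc.astype(float))
        self.sigma_beta = np.where(acc, prop_sd, self.sigma_beta)

    def update_group_moves(self):
        """Joint scale/translate moves along the hierarchical funnel.

        Hierarchical logit models develop a funnel: when a hyper-SD drifts
        toward 0 the species effects are pinned to the hyper-mean and
        neither can escape by individual random walks.  The remedy is a
        group move that transforms the hyper-pair and all K species values
        together: sigma' = sigma e^s, mu' = mu + t, theta'_k = mu' +
        (theta_k - mu) e^s.  The Gaussian prior ratio contributes -K s, the
        Jacobian of the (K+1)-dimensional scaling contributes (K+1) s, so
        the acceptance ratio reduces to [likelihood change] + s +
        [hyper-mean prior change]; the uniform hyper-SD prior only gates
        the support.
        """
        if self.fixed:
            return
        pr = self.cfg.priors
        M = self.M

        # slopes, one covariate at a time (they share the linear predictor)
        for c in range(self.C):
            s = self.steps["group_beta"][:, c] * self.rng.standard_normal(M)
            t = self.steps["group_beta"][:, c] * self.rng.standard_normal(M)
            mu, sd, cur = self.mu_beta[:, c], self.sigma_beta[:, c], self.beta[:, c, :]
            mu_p = mu + t
            sd_p = sd * np.exp(s)
            prop = mu_p[:, None] + (cur - mu[:, None]) * np.exp(s)[:, None]
            eta_prop = self.eta + self.X[None, :, c, None] * (prop - cur)[:, None, :]
            zll_prop = self._z_loglik(eta_prop)
            delta = (
                (zll_prop - self.zll).sum(axis=1) + s
                - 0.5 * (mu_p**2 - mu**2) / pr.mean_sd**2
            )
            delta = np.where(sd_p <= pr.sigma_upper, delta, -np.inf)
            acc = np.log(self.rng.random(M)) < delta
            rate = np.zeros((M, self.C))
            rate[:, c] = acc.astype(float)
            self.acc["group_beta"] += rate
            self.acc_total["group_beta"] += rate
            self.mu_beta[:, c] = np.where(acc, mu_p, mu)
            self.sigma_beta[:, c] = np.where(acc, sd_p, sd)
            self.beta[:, c, :] = np.where(acc[:, None], prop, cur)
            self.eta = np.where(acc[:, None, None], eta_prop, self.eta)
            self.zll = np.where(acc[:, None], zll_prop, self.zll)
        self.tries["group_beta"] += 1.0
        self.tries_total["group_beta"] += 1.0

        # occupancy intercepts: (mu_a, sigma_a, a_1..K).  The standardized
        # residual (a - mu_a)/sigma_a is invariant, so the bivariate prior's
        # quadratic form is unchanged and the same s-term survives.
        s = self.steps["group_a"] * self.rng.standard_normal(M)
        t = self.steps["group_a"] * self.rng.standard_normal(M)
        mu_p = self.mu_a + t
        sd_p = self.sigma_a * np.exp(s)
        prop = mu_p[:, None] + (self.a - self.mu_a[:, None]) * np.exp(s)[:, None]
        eta_prop = self.eta + (prop - self.a)[:, None, :]
        zll_prop = self._z_loglik(eta_prop)
        delta = (
            (zll_prop - self.zll).sum(axis=1) + s
            - 0.5 * (mu_p**2 - self.mu_a**2) / pr.mean_sd**2
        )
        delta = np.where(sd_p <= pr.sigma_upper, delta, -np.inf)
        acc = np.log(self.rng.random(M)) < delta
        self._track("group_a", acc.astype(float))
        self.mu_a = np.where(acc, mu_p, self.mu_a)
        self.sigma_a = np.where(acc, sd_p, self.sigma_a)
        self.a = np.where(acc[:, None], prop, self.a)
        self.eta = np.where(acc[:, None, None], eta_prop, self.eta)
        self.zll = np.where(acc[:, None], zll_prop, self.zll)

        # detection intercepts: (mu_b, sigma_b, b_1..K)
        s = self.steps["group_b"] * self.rng.standard_normal(M)
        t = self.steps["group_b"] * self.rng.standard_normal(M)
        mu_p = self.mu_b + t
        sd_p = self.sigma_b * np.exp(s)
        prop = mu_p[:, None] + (self.b - self.mu_b[:, None]) * np.exp(s)[:, None]
        dll_prop = self._det_loglik(prop)
        delta = (
            (dll_prop - self.dll).sum(axis=1) + s
            - 0.5 * (mu_p**2 - self.mu_b**2) / pr.mean_sd**2
        )
        delta = np.where(sd_p <= pr.sigma_upper, delta, -np.inf)
        acc = np.log(self.rng.random(M)) < delta
        self._track("group_b", acc.astype(float))
        self.mu_b = np.where(acc, mu_p, self.mu_b)
        self.sigma_b = np.where(acc, sd_p, self.sigma_b)
        self.b = np.where(acc[:, None], prop, self.b)
        self.dll = np.where(acc[:, None], dll_prop, self.dll)

    def adapt(self):
        """Rescale per-chain step sizes toward the target acceptance rate."""
        for key, step in self.steps.items():
            if self.tries[key] == 0:
                continue
            rate = self.acc[key] / self.tries[key]
            factor = np.exp(np.clip(rate - self.cfg.target_accept, -0.5, 0.5))
            self.steps[key] = np.clip(step * factor, 1e-3, 20.0)
            self.acc[key] = np.zeros_like(step)
            self.tries[key] = 0.0

    def sweep(self):
        self.update_z()
        self.update_a()
        self.update_b()
        self.update_beta()
        self.update_hypers()
        self.update_group_moves()

    def mean_acceptance(self) -> dict[str, float]:
        return {
            k: float(np.mean(self.acc_total[k])) / self.tries_total[k]
            for k in self.steps
            if self.tries_total[k] > 0
        }


def sample_posterior(
    data: DetectionHistory,
    covariates: SiteCovariates | np.ndarray,
    config: MCMCConfig | None = None,
) -> PosteriorChains:
    """Run the Metropolis-within-Gibbs sampler and return post-burn-in draws.

    ``covariates`` may be a standardized :class:`SiteCovariates` or a plain
    (S, C) design matrix (useful for small test problems with fewer than
    five covariates).  All chains advance together from one seeded RNG, so
    the full run is reproducible; chains differ through their random
    initial values and independent proposal noise.
    """
    config = config or MCMCConfig()
    if isinstance(covariates, SiteCovariates):
        X = covariates.x
        feature_names = covariates.feature_names
    else:
        X = np.asarray(covariates, dtype=float)
        feature_names = tuple(f"x{c+1}" for c in range(X.shape[1]))
    if X.shape[0] != data.n_sites:
        raise ParameterError("covariate rows must match number of sites")
    if data.n_sites < 2:
        raise ParameterError("need at least 2 sites")

    D = data.detections_per_site()
    J = data.surveys_per_site
    S, K = D.shape
    M = config.n_chains

    thin = max(1, (config.n_iter - config.burn_in) // config.n_keep)
    kept_per_chain = (config.n_iter - config.burn_in) // thin

    hyper_names = ["mu_a", "sigma_a", "mu_b", "sigma_b", "rho"] + [
        f"mu_beta_{name}" for name in feature_names
    ] + [f"sigma_beta_{name}" for name in feature_names]
    hyper_draws = {n: np.empty((M, kept_per_chain)) for n in hyper_names}
    species_draws = {
        "a": np.empty((M, kept_per_chain, K)),
        "b": np.empty((M, kept_per_chain, K)),
    }
    for name in feature_names:
        species_draws[f"beta_{name}"] = np.empty((M, kept_per_chain, K))
    z_draws = np.empty((M, kept_per_chain, S, K), dtype=np.uint8)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    chains = _VectorChains(rng, X, D, J, config, K)
    kept = 0
    for it in range(config.n_iter):
        chains.sweep()
        in_burn = it < config.burn_in
        if in_burn and (it + 1) % config.adapt_interval == 0:
            chains.adapt()
        if not in_burn and (it - config.burn_in) % thin == thin - 1 and kept < kept_per_chain:
            hyper_draws["mu_a"][:, kept] = chains.mu_a
            hyper_draws["sigma_a"][:, kept] = chains.sigma_a
            hyper_draws["mu_b"][:, kept] = chains.mu_b
            hyper_draws["sigma_b"][:, kept] = chains.sigma_b
            hyper_draws["rho"][:, kept] = chains.rho
            for c, name in enumerate(feature_names):
                hyper_draws[f"mu_beta_{name}"][:, kept] = chains.mu_beta[:, c]
                hyper_draws[f"sigma_beta_{name}"][:, kept] = chains.sigma_beta[:, c]
                species_draws[f"beta_{name}"][:, kept] = chains.beta[:, c, :]
            species_draws["a"][:, kept] = chains.a
            species_draws["b"][:, kept] = chains.b
            z_draws[:, kept] = chains.z
            kept += 1

    if config.fix_hypers is not None:
        # hyper-parameters were constants; drop their (flat) chains
        hyper_draws = {}

    return PosteriorChains(
        hyper_draws=hyper_draws,
        species_draws=species_draws,
        z_draws=z_draws,
        site_ids=list(data.site_ids),
        species_names=list(data.species_names),
        feature_names=feature_names,
        config=config,
        acceptance_rates=chains.mean_acceptance(),
    )


# ---------------------------------------------------------------------------
# Diagnostics and derived quantities
# ---------------------------------------------------------------------------


def gelman_rubin(chains: np.ndarray) -> float:
    """Classic Gelman-Rubin potential scale reduction factor.

    ``chains`` is (m, n): m >= 2 chains of n >= 10 kept draws.  Computes
    within-chain variance W, between-chain variance B, the pooled posterior
    variance estimate ((n-1)/n) W + B/n, and returns sqrt of their ratio.
    Returns nan when every chain has zero variance (undefined diagnostic).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ParameterError("need an (m >= 2, n) array of draws")
    m, n = chains.shape
    if n < 2:
        raise ParameterError("need at least 2 draws per chain")
    W = chains.var(axis=1, ddof=1).mean()
    if W == 0.0:
        return float("nan")
    B_over_n = chains.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def derived_richness(chains: PosteriorChains) -> RichnessPosterior:
    """Per-site species richness from posterior draws of the occurrence
    matrix: N_i = sum_k z_ik per draw, summarized by the posterior mean and
    central 95% interval."""
    draws = chains.z_draws.sum(axis=3).reshape(-1, chains.z_draws.shape[2]).astype(float)
    return RichnessPosterior(
        draws=draws,
        mean=draws.mean(axis=0),
        lower=np.percentile(draws, 2.5, axis=0),
        upper=np.percentile(draws, 97.5, axis=0),
        site_ids=list(chains.site_ids),
    )


def summarize_community_effects(chains: PosteriorChains) -> pd.DataFrame:
    """Posterior summary of the community hyper-parameters.

    For every slope hyper-mean mu_beta_c: posterior mean, central 95%
    interval, and a significance flag set when the interval excludes zero.
    Covariates are distances, so a *negative* significant hyper-mean means
    richness increases with proximity to that feature class.  Warns (but
    still summarizes) if any monitored Rhat is >= 1.1.
    """
    rhats = chains.rhat_table()
    bad = rhats[rhats["rhat"] >= 1.1]
    if len(bad):
        warnings.warn(
            "convergence not reached (Rhat >= 1.1) for: "
            + ", ".join(bad["parameter"]),
            stacklevel=2,
        )
    rows = []
    for name, draws in chains.hyper_draws.items():
        flat = draws.reshape(-1)
        lo, hi = np.percentile(flat, [2.5, 97.5])
        rows.append(
            {
                "parameter": name,
                "mean": flat.mean(),
                "2.5%": lo,
                "97.5%": hi,
                "significant": bool(name.startswith("mu_beta") and (lo > 0 or hi < 0)),
            }
        )
    return pd.DataFrame(rows)
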