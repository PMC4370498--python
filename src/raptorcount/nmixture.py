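"""Negative-binomial N-mixture models for single-species abundance.

Repeated point counts y_ij at site i, replicate j, are modelled as
binomial thinnings of a latent site abundance N_i:

    N_i  ~ NegBin(lambda_i, alpha)        (ecological process)
    y_ij ~ Binomial(N_i, p)               (observational process)

with log(lambda_i) = alpha_0 + sum_c beta_c x_ic on the standardized
distance covariates, a single detection probability p = inv-logit(eta)
shared by all sites and replicates, and the "ecological" negative-binomial
parameterization: mean lambda, overdispersion alpha, variance
lambda + lambda^2 / alpha (Poisson in the alpha -> infinity limit).
Negative-binomial conventions differ between packages — here larger alpha
always means *less* overdispersion.

The latent abundance is marginalized by a truncated sum over
N = max_j(y_ij) .. K, with K chosen so the neglected upper tail is below a
small tolerance.  Fitting is by maximum likelihood (quasi-Newton with
multiple random starts, because the (lambda, p) profile of N-mixture
likelihoods can be multimodal), standard errors come from the inverse
observed information, and per-coefficient inference is Wald: z = est/SE
against the standard normal, starred at the p <= 0.1 / 0.05 / 0.01 levels.
Because the covariates are *distances* to human constructions, a negative
coefficient means abundance increases with proximity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, gammaln, logsumexp

from .data import SiteCovariates, SurveyCounts

STAR_THRESHOLDS = ((0.01, "***"), (0.05, "**"), (0.1, "*"))


class ParameterError(ValueError):
    """Parameter outside its legal domain."""


class TruncationError(ValueError):
    """Truncation bound K below the maximum observed count."""


class UnidentifiableError(ValueError):
    """Data cannot identify the model (e.g. all counts zero)."""


class FitError(RuntimeError):
    """Optimization failed on every start."""


@dataclass
class NMixtureParams:
    """Parameters of the negative-binomial N-mixture model.

    alpha0     : abundance intercept on the log scale
    beta       : (C,) coefficients of the standardized distance covariates
    alpha_disp : NB overdispersion, > 0 (Var = lambda + lambda^2/alpha_disp)
    eta        : detection intercept on the logit scale, p = inv-logit(eta)
    """

    alpha0: float
    beta: np.ndarray
    alpha_disp: float
    eta: float

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if not self.alpha_disp > 0:
            raise ParameterError("alpha_disp must be positive")
        if not np.all(np.isfinite([self.alpha0, self.eta])) or not np.all(
            np.isfinite(self.beta)
        ):
            raise ParameterError("parameters must be finite")

    @property
    def p(self) -> float:
        return float(expit(self.eta))

    def lam(self, X: np.ndarray) -> np.ndarray:
        """Expected abundance per site: exp(alpha0 + X beta)."""
        return np.exp(self.alpha0 + np.asarray(X, dtype=float) @ self.beta)


@dataclass
class NMixtureFit:
    """Maximum-likelihood fit of one N-mixture model."""

    feature_names: tuple[str, ...]
    estimates: np.ndarray  # (C + 3,) order: alpha0, beta_1..C, log_alpha_disp, eta
    se: np.ndarray
    loglik: float
    K: int
    converged: bool
    boundary: bool  # p-hat or alpha_disp pinned at the edge; SEs unreliable
    n_sites: int
    vcov: np.ndarray | None = None
    # Wald inference, filled by wald_inference()
    z: np.ndarray | None = None
    pvalues: np.ndarray | None = None
    stars: list[str] | None = None

    @property
    def param_names(self) -> tuple[str, ...]:
        return ("alpha0", *self.feature_names, "log_alpha_disp", "eta")

    @property
    def n_covariates(self) -> int:
        return len(self.feature_names)

    @property
    def params(self) -> NMixtureParams:
        c = self.n_covariates
        return NMixtureParams(
            alpha0=float(self.estimates[0]),
            beta=self.estimates[1 : 1 + c].copy(),
            alpha_disp=float(np.exp(self.estimates[1 + c])),
            eta=float(self.estimates[2 + c]),
        )

    def coefficient_table(self):
        import pandas as pd

        if self.pvalues is None:
            raise ParameterError("run wald_inference first")
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "estimate": self.estimates,
                "se": self.se,
                "z": self.z,
                "p": self.pvalues,
                "stars": self.stars,
            }
        )


@dataclass
class NMixtureConfig:
    """Fitting configuration: number of random starts, seed, truncation."""

    n_starts: int = 5
    seed: int = 0
    truncation_tol: float = 1e-8
    K: int | None = None  # None -> chosen automatically and stability-checked
    K_max: int = 3000  # hard cap on the automatic truncation bound
    maxiter: int = 1000


# ---------------------------------------------------------------------------
# Distribution primitives
# ---------------------------------------------------------------------------


def negbin_pmf(n, lam, alpha):
    """Negative-binomial mass with mean ``lam`` and overdispersion ``alpha``.

    Var = lam + lam^2/alpha.  Equivalent to scipy's nbinom with size alpha
    and success probability alpha / (alpha + lam).
    """
    lam = np.asarray(lam, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(lam <= 0) or np.any(alpha <= 0):
        raise ParameterError("lam and alpha must be positive")
    return stats.nbinom.pmf(n, alpha, alpha / (alpha + lam))


def negbin_logpmf(n, lam, alpha):
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0) or alpha <= 0:
        raise ParameterError("lam and alpha must be positive")
    n = np.asarray(n)
    return (
        gammaln(n + alpha)
        - gammaln(alpha)
        - gammaln(n + 1)
        + alpha * (np.log(alpha) - np.log(alpha + lam))
        + n * (np.log(lam) - np.log(alpha + lam))
    )


def choose_truncation_K(
    counts: SurveyCounts | np.ndarray, lam_upper: float, alpha: float, tol: float = 1e-8
) -> int:
    """Upper summation bound for the latent-abundance marginalization.

    Returns the smallest K that is at least the maximum observed count and
    leaves negative-binomial upper-tail mass below ``tol`` at the largest
    plausible site mean ``lam_upper``.
    """
    if tol <= 0:
        raise ParameterError("tol must be positive")
    max_count = int(np.max(counts.counts if isinstance(counts, SurveyCounts) else counts))
    k_tail = int(stats.nbinom.ppf(1.0 - tol, alpha, alpha / (alpha + lam_upper)))
    return max(max_count, k_tail)


def site_log_marginal(y, lam, p, alpha, K) -> float:
    """Log marginal likelihood of one site's counts.

    log sum_{N=max(y)}^{K} NegBin(N; lam, alpha) prod_j Binomial(y_j; N, p),
    the product running over the surveyed replicates only; evaluated in log
    space.
    """
    y = np.asarray(y, dtype=int)
    if K < y.max(initial=0):
        raise TruncationError(f"K={K} below max observed count {y.max()}")
    ns = np.arange(int(K) + 1)
    lp_n = negbin_logpmf(ns, lam, alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp_y = stats.binom.logpmf(y[:, None], ns[None, :], p).sum(axis=0)
    return float(logsumexp(lp_n + lp_y))


def _log_sigmoid(t):
    return -np.logaddexp(0.0, -t)


def _precompute_marginal(y: np.ndarray, mask: np.ndarray, K: int) -> dict:
    """Parameter-independent pieces of the truncated marginal likelihood.

    The binomial coefficients sum_j log C(N, y_ij) over surveyed replicates,
    the per-site totals Y_i and survey counts J_i, and the latent-abundance
    grid N = 0..K.  Computing these once makes each likelihood evaluation a
    handful of (S, K+1) array operations.
    """
    ns = np.arange(K + 1)
    yf = y.astype(float)
    comb = (
        gammaln(ns[None, None, :] + 1.0)
        - gammaln(yf[:, :, None] + 1.0)
        - gammaln(np.maximum(ns[None, None, :] - yf[:, :, None], -0.5) + 1.0)
    )
    comb = np.where(ns[None, None, :] >= yf[:, :, None], comb, -np.inf)
    comb = np.where(mask[:, :, None], comb, 0.0)
    return {
        "ns": ns,
        "gl_ns": gammaln(ns + 1.0),
        "comb_sum": comb.sum(axis=1),  # (S, K+1)
        "Y": np.where(mask, yf, 0.0).sum(axis=1),  # (S,)
        "J": mask.sum(axis=1).astype(float),  # (S,)
    }


def _negloglik_pre(theta: np.ndarray, pre: dict, X: np.ndarray) -> float:
    C = X.shape[1]
    alpha0 = theta[0]
    beta = theta[1 : 1 + C]
    alpha = np.exp(np.clip(theta[1 + C], -30.0, 30.0))
    eta = theta[2 + C]
    log_p = _log_sigmoid(eta)
    log_1mp = _log_sigmoid(-eta)

    log_lam = np.clip(alpha0 + X @ beta, -30.0, 30.0)
    lam = np.exp(log_lam)
    log_ap = np.log(alpha + lam)  # (S,)
    ns = pre["ns"]
    nb_lp = (
        (gammaln(ns + alpha) - gammaln(alpha) - pre["gl_ns"])[None, :]
        + alpha * (np.log(alpha) - log_ap)[:, None]
        + ns[None, :] * (log_lam - log_ap)[:, None]
    )
    bin_lp = (
        pre["comb_sum"]
        + pre["Y"][:, None] * log_p
        + (ns[None, :] * pre["J"][:, None] - pre["Y"][:, None]) * log_1mp
    )
    return -float(logsumexp(nb_lp + bin_lp, axis=1).sum())


def _negloglik_theta(theta: np.ndarray, y: np.ndarray, mask: np.ndarray, X: np.ndarray, K: int):
    """Vectorized negative log-likelihood over all sites.

    theta = (alpha0, beta_1..C, log_alpha_disp, eta); y is the (S, Jmax)
    count matrix of a single species with its survey mask.
    """
    return _negloglik_pre(theta, _precompute_marginal(y, mask, K), X)


def _single_species(counts: SurveyCounts) -> tuple[np.ndarray, np.ndarray]:
    if counts.n_species != 1:
        raise ParameterError(
            "N-mixture models are fit to one species at a time; use "
            "select_species() or total_abundance() first"
        )
    return counts.counts[:, :, 0], counts.replicate_mask


def nmixture_negloglik(
    params: NMixtureParams, counts: SurveyCounts, covs: SiteCovariates, K: int
) -> float:
    """Negative log-likelihood of a single-species dataset under ``params``."""
    y, mask = _single_species(counts)
    if counts.counts.sum() == 0:
        raise UnidentifiableError("species has zero total count; model unidentifiable")
    theta = np.concatenate(
        [[params.alpha0], params.beta, [np.log(params.alpha_disp)], [params.eta]]
    )
    return _negloglik_theta(theta, y, mask, covs.x, K)


# ---------------------------------------------------------------------------
# Fitting and inference
# ---------------------------------------------------------------------------


def _initial_points(y, mask, C, n_starts, rng):
    """One heuristic start plus random perturbations around it."""
    site_max = np.where(mask, y, 0).max(axis=1)
    mean_max = max(site_max.mean(), 0.5)
    starts = []
    for p0 in (0.25, 0.5):
        theta = np.zeros(C + 3)
        theta[0] = np.log(mean_max / p0)
        theta[C + 1] = 0.0  # alpha_disp = 1
        theta[C + 2] = np.log(p0 / (1 - p0))
        starts.append(theta)
    while len(starts) < n_starts:
        theta = starts[0] + rng.normal(0.0, [1.0] * (C + 1) + [1.0, 1.5])
        starts.append(theta)
    return starts[:n_starts]


def _numeric_hessian(fun, theta, eps=1e-4):
    """Central-difference Hessian of a scalar function."""
    n = len(theta)
    H = np.empty((n, n))
    h = eps * np.maximum(1.0, np.abs(theta))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            f_pp = fun(theta + ei + ej)
            f_pm = fun(theta + ei - ej)
            f_mp = fun(theta - ei + ej)
            f_mm = fun(theta - ei - ej)
            H[i, j] = H[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4.0 * h[i] * h[j])
    return H


def fit_nmixture(
    counts: SurveyCounts, covs: SiteCovariates, config: NMixtureConfig | None = None
) -> NMixtureFit:
    """Fit the negative-binomial N-mixture model by maximum likelihood.

    Multi-start quasi-Newton minimization of the truncated marginal
    negative log-likelihood; the truncation bound K is enlarged and the fit
    repeated until the log-likelihood is stable to 1e-6 under a further
    increase of K.  Standard errors come from the inverse of a
    finite-difference observed information matrix at the optimum.  Boundary
    estimates (p-hat near 0 or 1, or alpha_disp effectively infinite) are
    flagged and their SEs marked unreliable.
    """
    config = config or NMixtureConfig()
    y, mask = _single_species(counts)
    if y.sum() == 0:
        raise UnidentifiableError("species has zero total count; model unidentifiable")
    X = covs.x
    if X.shape[0] != counts.n_sites:
        raise ParameterError("covariate rows must match number of sites")
    C = X.shape[1]
    rng = np.random.default_rng(config.seed)

    max_count = int(y.max())
    K = config.K if config.K is not None else min(
        max(3 * max_count + 50, 100), config.K_max
    )
    # generous box constraints keep the optimizer off the lambda -> inf /
    # p -> 0 ridge that N-mixture likelihoods develop on sparse data
    bounds = (
        [(-10.0, 12.0)] + [(-10.0, 10.0)] * C + [(-7.0, 12.0)] + [(-12.0, 12.0)]
    )

    best = None
    truncation_capped = False
    for attempt in range(4):
        pre = _precompute_marginal(y, mask, K)
        nll = lambda th: _negloglik_pre(th, pre, X)
        # after the first attempt K only grew, so the previous optimum is an
        # excellent warm start and the multi-start search need not repeat
        starts = (
            _initial_points(y, mask, C, config.n_starts, rng)
            if best is None
            else [best.x.copy()]
        )
        best = None
        for theta0 in starts:
            try:
                res = optimize.minimize(
                    nll, np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds]),
                    method="L-BFGS-B", bounds=bounds,
                    options={"maxiter": config.maxiter},
                )
            except (FloatingPointError, ValueError):
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise FitError("all optimizer starts failed")
        if config.K is not None:
            break
        # enlarge K until the truncated likelihood has converged
        alpha_hat = np.exp(best.x[C + 1])
        lam_hat = np.exp(np.clip(best.x[0] + X @ best.x[1 : 1 + C], -30, 30))
        K_needed = min(
            choose_truncation_K(
                y, float(lam_hat.max()), float(alpha_hat), config.truncation_tol
            ),
            config.K_max,
        )
        stable = abs(
            _negloglik_theta(best.x, y, mask, X, min(int(K * 1.5) + 10, config.K_max + 500))
            - best.fun
        ) < 1e-6
        if (K >= K_needed and stable) or K >= config.K_max:
            truncation_capped = K >= config.K_max and not stable
            break
        K = min(max(K_needed, int(K * 1.5) + 10), config.K_max)

    theta_hat = best.x
    loglik = -best.fun
    p_hat = float(expit(theta_hat[C + 2]))
    alpha_hat = float(np.exp(theta_hat[C + 1]))
    boundary = (
        p_hat < 1e-4 or p_hat > 1 - 1e-4 or alpha_hat > 1e4 or truncation_capped
        or bool(np.any(np.isclose(theta_hat, [b[0] for b in bounds]))
                or np.any(np.isclose(theta_hat, [b[1] for b in bounds])))
    )

    pre = _precompute_marginal(y, mask, K)
    H = _numeric_hessian(lambda th: _negloglik_pre(th, pre, X), theta_hat)
    try:
        vcov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
        if np.any(np.diag(vcov) <= 0):
            boundary = True
    except np.linalg.LinAlgError:
        vcov = None
        se = np.full(C + 3, np.nan)
        boundary = True

    grad_ok = np.all(np.abs(best.jac) < 1e-2) if best.jac is not None else True
    fit = NMixtureFit(
        feature_names=tuple(covs.feature_names[:C]) if hasattr(covs, "feature_names") else tuple(f"x{i+1}" for i in range(C)),
        estimates=theta_hat,
        se=se,
        loglik=loglik,
        K=int(K),
        converged=bool(best.success or grad_ok),
        boundary=bool(boundary),
        n_sites=counts.n_sites,
        vcov=vcov,
    )
    return wald_inference(fit)


def significance_stars(p: float) -> str:
    """Star code for a two-sided p-value: * p<=0.1, ** p<=0.05, *** p<=0.01."""
    for thr, stars in STAR_THRESHOLDS:
        if p <= thr:
            return stars
    return ""


def wald_pvalue(estimate: float, se: float) -> float:
    """Two-sided normal p-value for a Wald test of estimate/SE against 0."""
    if se <= 0:
        raise ParameterError("SE must be positive for a Wald test")
    return float(2.0 * stats.norm.sf(abs(estimate) / se))


def wald_inference(fit: NMixtureFit) -> NMixtureFit:
    """Fill per-coefficient Wald z, two-sided p, and significance stars."""
    with np.errstate(divide="ignore", invalid="ignore"):
        z = fit.estimates / fit.se
    p = 2.0 * stats.norm.sf(np.abs(z))
    fit.z = z
    fit.pvalues = p
    fit.stars = ["" if not np.isfinite(pv) else significance_stars(pv) for pv in p]
    return fit


def detection_probability_ci(fit: NMixtureFit, level: float = 0.95):
    """Detection probability with a Wald interval built on the logit scale
    and back-transformed, so the bounds always lie in (0, 1) and bracket
    the point estimate."""
    c = fit.n_covariates
    eta, se_eta = float(fit.estimates[c + 2]), float(fit.se[c + 2])
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    lo = float(expit(eta - zcrit * se_eta))
    hi = float(expit(eta + zcrit * se_eta))
    return float(expit(eta)), lo, hi


def most_influential_effect(
    estimates, pvalues=None, feature_names=None, gate: float = 0.1
) -> str | None:
    """Name of the most influential covariate in a fitted model.

    Among distance coefficients whose Wald p-value passes the reporting
    gate (p <= 0.1), returns the one with the largest absolute standardized
    estimate; returns None when no coefficient passes.  Accepts either an
    :class:`NMixtureFit` or parallel arrays of coefficient estimates and
    p-values.
    """
    if isinstance(estimates, NMixtureFit):
        fit = estimates
        if fit.pvalues is None:
            raise ParameterError("run wald_inference first")
        c = fit.n_covariates
        names = fit.feature_names
        est = fit.estimates[1 : 1 + c]
        pv = fit.pvalues[1 : 1 + c]
    else:
        est = np.asarray(estimates, dtype=float)
        pv = np.asarray(pvalues, dtype=float)
        names = tuple(feature_names) if feature_names is not None else tuple(
            f"x{i+1}" for i in range(len(est))
        )
    eligible = [(abs(e), n) for e, p_, n in zip(est, pv, names) if p_ <= gate]
    if not eligible:
        return None
    return max(eligible)[1]
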