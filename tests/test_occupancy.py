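"""Multi-species occupancy model: likelihood, Gibbs step, MCMC, diagnostics."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import multivariate_normal, norm

from raptorcount import (
    CommunityHyperParams,
    DetectionHistory,
    MCMCConfig,
    OccupancyState,
    PriorConfig,
    SpeciesEffects,
    derived_richness,
    gelman_rubin,
    log_joint,
    occupancy_probability,
    sample_posterior,
    simulate_community,
    summarize_community_effects,
    z_full_conditional,
)
from raptorcount.occupancy import ParameterError

from conftest import make_design


def _history(detections, mask=None):
    det = np.asarray(detections)
    if mask is None:
        mask = np.ones(det.shape[:2], dtype=bool)
    return DetectionHistory(
        detections=det,
        replicate_mask=np.asarray(mask, dtype=bool),
        site_ids=[f"s{i}" for i in range(det.shape[0])],
        species_names=[f"k{i}" for i in range(det.shape[2])],
    )


class TestOccupancyProbability:
    def test_zero_coefficients_give_half(self):
        assert occupancy_probability(0.0, np.zeros(5), np.random.default_rng(0).normal(size=5)) == 0.5

    def test_intercept_closed_form(self):
        assert occupancy_probability(2.0, np.zeros(5), np.zeros(5)) == pytest.approx(
            1 / (1 + np.exp(-2)), abs=1e-12
        )

    def test_negative_slope_means_higher_occupancy_near_feature(self):
        # distance covariate: negative coefficient -> occupancy falls as
        # the (standardized) distance grows
        psi_far = occupancy_probability(0.0, np.array([-1.0]), np.array([1.0]))
        assert psi_far == pytest.approx(expit(-1.0), abs=1e-10)
        grid = np.linspace(-3, 3, 25)
        psis = [occupancy_probability(0.0, np.array([-1.0]), np.array([x])) for x in grid]
        assert np.all(np.diff(psis) < 0)


class TestZFullConditional:
    def test_detection_implies_occupancy(self):
        assert z_full_conditional(0.3, 0.2, 5, 2) == 1.0

    def test_bayes_rule_by_hand(self):
        # psi (1-p)^J / (psi (1-p)^J + 1 - psi) = 0.25 / 0.75
        assert z_full_conditional(0.5, 0.5, 1, 0) == pytest.approx(1 / 3, abs=1e-12)

    def test_certain_occupancy(self):
        assert z_full_conditional(1.0, 0.7, 4, 0) == 1.0

    def test_normalizes_over_z(self):
        q = z_full_conditional(0.37, 0.21, 6, 0)
        assert 0.0 <= q <= 1.0
        # the two z states exhaust the conditional
        assert q + (1 - q) == pytest.approx(1.0, abs=1e-15)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ParameterError):
            z_full_conditional(0.5, 0.5, 2, 3)


def _toy_state():
    """2 sites x 2 species toy with full hyper-structure."""
    hyper = CommunityHyperParams(
        mu_a=0.2, sigma_a=1.1, mu_b=-0.4, sigma_b=0.8, rho=0.5,
        mu_beta=np.array([0.1]), sigma_beta=np.array([0.9]),
    )
    effects = SpeciesEffects(
        a=np.array([0.3, -0.6]), b=np.array([-0.2, 0.7]),
        beta=np.array([[0.5, -1.0]]),
    )
    z = np.array([[1, 1], [1, 0]])
    det = np.zeros((2, 3, 2), dtype=int)
    det[0, 0, 0] = 1
    det[0, 2, 1] = 1
    mask = np.array([[True, True, True], [True, True, False]])
    return OccupancyState(z=z, effects=effects, hyper=hyper), _history(det, mask), np.array([[0.4], [-1.3]])


class TestLogJoint:
    def test_single_cell_hand_value(self):
        # one site, one species, one survey with a detection; psi = p = 0.5
        # and a point-mass hyper-structure: only z-prior x observation remain
        hyper = CommunityHyperParams(0.0, 0.0, 0.0, 0.0, 0.0, np.zeros(1), np.zeros(1))
        state = OccupancyState(
            z=np.array([[1]]),
            effects=SpeciesEffects(a=[0.0], b=[0.0], beta=[[0.0]]),
            hyper=hyper,
        )
        hist = _history(np.array([[[1]]]))
        lp = log_joint(state, hist, np.array([[0.0]]), priors=None)
        assert lp == pytest.approx(np.log(0.25), abs=1e-12)

    def test_data_term_additivity(self):
        state, hist, X = _toy_state()
        # duplicate every site: data-dependent part doubles
        state2 = OccupancyState(
            z=np.vstack([state.z, state.z]), effects=state.effects, hyper=state.hyper
        )
        hist2 = _history(
            np.vstack([hist.detections, hist.detections]),
            np.vstack([hist.replicate_mask, hist.replicate_mask]),
        )
        X2 = np.vstack([X, X])
        lp1 = log_joint(state, hist, X, priors=None)
        lp2 = log_joint(state2, hist2, X2, priors=None)
        # effect-density terms are identical in both, so subtracting them
        # isolates the data-dependent part, which must double
        ed = _effect_density(state)
        assert lp2 - ed == pytest.approx(2.0 * (lp1 - ed), abs=1e-9)

    def test_matches_term_by_term_oracle(self):
        state, hist, X = _toy_state()
        lp = log_joint(state, hist, X, priors=PriorConfig())
        assert lp == pytest.approx(_oracle_log_joint(state, hist, X, PriorConfig()), abs=1e-10)

    def test_inconsistent_state_is_impossible(self):
        state, hist, X = _toy_state()
        bad = OccupancyState(
            z=np.zeros_like(state.z), effects=state.effects, hyper=state.hyper
        )
        assert log_joint(bad, hist, X, priors=None) == -np.inf


def _effect_density(state):
    """Species-effect log-density under the hyper-distributions (oracle)."""
    h = state.hyper
    e = state.effects
    cov = np.array(
        [
            [h.sigma_a**2, h.rho * h.sigma_a * h.sigma_b],
            [h.rho * h.sigma_a * h.sigma_b, h.sigma_b**2],
        ]
    )
    lp = sum(
        multivariate_normal.logpdf([e.a[k], e.b[k]], [h.mu_a, h.mu_b], cov)
        for k in range(len(e.a))
    )
    for c in range(h.n_covariates):
        lp += norm.logpdf(e.beta[c], h.mu_beta[c], h.sigma_beta[c]).sum()
    return lp


def _oracle_log_joint(state, hist, X, priors):
    """Brute-force term-by-term evaluation, replicate by replicate."""
    e, h = state.effects, state.hyper
    S, K = state.z.shape
    lp = 0.0
    for i in range(S):
        for k in range(K):
            psi = expit(e.a[k] + float(X[i] @ e.beta[:, k]))
            p = expit(e.b[k])
            z = state.z[i, k]
            lp += np.log(psi if z else 1 - psi)
            for j in range(hist.detections.shape[1]):
                if not hist.replicate_mask[i, j]:
                    continue
                y = hist.detections[i, j, k]
                pr = p * z if y else 1 - p * z
                lp += np.log(pr)
    lp += _effect_density(state)
    for mu in (h.mu_a, h.mu_b, *h.mu_beta):
        lp += norm.logpdf(mu, 0, priors.mean_sd)
    for _ in range(2 + h.n_covariates):
        lp += np.log(1 / priors.sigma_upper)
    lp += np.log(0.5)  # rho ~ U(-1, 1)
    return lp


class TestGelmanRubin:
    def test_hand_computed_example(self):
        chains = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 7.0]])
        m, n = chains.shape
        W = chains.var(axis=1, ddof=1).mean()
        B_over_n = chains.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B_over_n) / W)
        assert gelman_rubin(chains) == pytest.approx(expected, abs=1e-12)

    def test_null_distribution_near_one(self):
        rng = np.random.default_rng(42)
        chains = rng.standard_normal((2, 10_000))
        r = gelman_rubin(chains)
        assert 1.0 - 1e-6 <= r <= 1.01

    def test_divergent_chains_flagged(self):
        rng = np.random.default_rng(43)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert gelman_rubin(chains) > 1.1

    def test_zero_variance_undefined(self):
        assert np.isnan(gelman_rubin(np.ones((2, 50))))

    def test_agrees_with_reference_implementation(self):
        import arviz

        rng = np.random.default_rng(7)
        chains = rng.normal(0, 1, (3, 400)) + np.array([[0.0], [0.3], [-0.2]])
        ours = gelman_rubin(chains)
        ref = float(arviz.rhat(arviz.convert_to_dataset(chains))["x"].values)
        # arviz uses the rank-normalized split-Rhat; agreement is approximate
        assert ours == pytest.approx(ref, abs=0.02)


@pytest.fixture(scope="module")
def small_fit():
    """A short MCMC run on a small simulated community, reused across tests."""
    design = make_design(np.random.default_rng(21).uniform(0, 10, (25, 2)), [6] * 25)
    hyper = CommunityHyperParams(
        mu_a=0.0, sigma_a=1.0, mu_b=0.0, sigma_b=0.7, rho=0.4,
        mu_beta=np.array([-1.0, 0.0]), sigma_beta=np.array([0.4, 0.4]),
    )
    hist, truth = simulate_community(hyper, design, n_species=6, seed=22)
    cfg = MCMCConfig(n_chains=2, n_iter=3000, seed=23, n_keep=500)
    return hist, design, sample_posterior(hist, design.covariates.x, cfg), cfg


class TestSampler:
    def test_deterministic_under_seed(self, small_fit):
        hist, design, post, cfg = small_fit
        again = sample_posterior(hist, design.covariates.x, cfg)
        np.testing.assert_array_equal(post.z_draws, again.z_draws)
        np.testing.assert_array_equal(
            post.hyper_draws["mu_beta_x1"], again.hyper_draws["mu_beta_x1"]
        )

    def test_z_respects_detections(self, small_fit):
        hist, design, post, _ = small_fit
        D = hist.detections_per_site()
        assert np.all(post.z_draws[:, :, D > 0] == 1)

    def test_needs_two_chains(self, small_fit):
        with pytest.raises(ParameterError):
            MCMCConfig(n_chains=1)


class TestDerivedRichness:
    def test_row_sum(self, small_fit):
        _, _, post, _ = small_fit
        rich = derived_richness(post)
        np.testing.assert_array_equal(
            rich.draws, post.z_draws.sum(axis=3).reshape(-1, post.z_draws.shape[2])
        )

    def test_bounds(self, small_fit):
        hist, _, post, _ = small_fit
        rich = derived_richness(post)
        observed = (hist.detections_per_site() > 0).sum(axis=1)
        assert np.all(rich.draws >= observed[None, :])
        assert np.all(rich.draws <= hist.n_species)

    def test_mean_is_exactly_the_draw_mean(self, small_fit):
        _, _, post, _ = small_fit
        rich = derived_richness(post)
        np.testing.assert_array_equal(rich.mean, rich.draws.mean(axis=0))


class TestSummaries:
    def test_symmetric_posterior_not_significant(self, small_fit):
        _, _, post, _ = small_fit
        fake = post.hyper_draws.copy()
        rng = np.random.default_rng(1)
        fake["mu_beta_x2"] = rng.normal(0.0, 1.0, fake["mu_beta_x2"].shape)
        post2 = type(post)(
            hyper_draws=fake, species_draws=post.species_draws, z_draws=post.z_draws,
            site_ids=post.site_ids, species_names=post.species_names,
            feature_names=post.feature_names, config=post.config,
            acceptance_rates=post.acceptance_rates,
        )
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = summarize_community_effects(post2).set_index("parameter")
        assert not table.loc["mu_beta_x2", "significant"]

    def test_strong_effect_recovered_and_sign_flip(self):
        """One covariate drives occupancy; flipping its sign flips the
        recovered hyper-mean."""
        design = make_design(np.random.default_rng(31).uniform(0, 10, (40, 1)), [8] * 40)
        hyper = CommunityHyperParams(
            mu_a=0.5, sigma_a=0.8, mu_b=0.5, sigma_b=0.5, rho=0.0,
            mu_beta=np.array([-1.5]), sigma_beta=np.array([0.4]),
        )
        hist, _ = simulate_community(hyper, design, n_species=8, seed=32)
        cfg = MCMCConfig(n_chains=2, n_iter=4000, seed=33, n_keep=500)
        post = sample_posterior(hist, design.covariates.x, cfg)
        post_neg = sample_posterior(hist, -design.covariates.x, cfg)
        m = post.hyper_draws["mu_beta_x1"].mean()
        m_neg = post_neg.hyper_draws["mu_beta_x1"].mean()
        assert m < -0.5  # strong negative effect found
        assert m_neg == pytest.approx(-m, abs=0.35)  # MCMC error, opposite sign
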