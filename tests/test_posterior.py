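"""Posterior CDF of the MTD: quadrature backend, quantiles, prior summaries."""

import numpy as np
import pytest
from scipy.special import expit, log_expit, logit

from ewoc import (DoseSpace, GridPosterior, PriorSpec, TrialData,
                  compute_posterior, log_likelihood, mtd_quantile,
                  prior_summary)
from ewoc.posterior import gamma_prior_mean_closed_form

THETA = 1.0 / 3.0


class TestLogLikelihood:
    def test_empty_data_is_zero(self):
        assert log_likelihood([], 250.0, 0.05, THETA, 140.0) == 0.0

    def test_non_dlt_at_xmin_gives_log_one_minus_rho0(self):
        ll = log_likelihood([(140.0, 0)], 200.0, 0.25, THETA, 140.0)
        assert ll == pytest.approx(np.log(0.75), abs=1e-12)

    def test_dlt_at_mtd_gives_log_theta(self):
        ll = log_likelihood([(250.0, 1)], 250.0, 0.05, THETA, 140.0)
        assert ll == pytest.approx(np.log(THETA), abs=1e-12)

    def test_outcomes_must_be_binary(self):
        with pytest.raises(ValueError):
            TrialData(((140.0, 2),))


class TestUniformPriorPosterior:
    def test_no_data_marginal_is_uniform(self, uniform_prior, cont_space):
        post = compute_posterior([], uniform_prior, cont_space)
        assert post.quantile(0.25) == pytest.approx(211.25, abs=1e-9)
        assert post.quantile(0.50) == pytest.approx(282.5, abs=1e-9)
        g = np.linspace(140, 425, 20)
        assert post.cdf_at(g) == pytest.approx((g - 140) / 285, abs=1e-9)

    def test_cdf_is_valid(self, uniform_prior, cont_space):
        data = [(140, 0), (183, 0), (215, 1)]
        post = compute_posterior(data, uniform_prior, cont_space)
        assert np.all(np.diff(post.cdf) >= 0)
        assert post.cdf[0] == 0.0
        assert post.cdf[-1] == pytest.approx(1.0)
        assert post.grid[0] == 140.0 and post.grid[-1] == 425.0

    def test_non_dlts_shift_mass_to_higher_doses(self, uniform_prior,
                                                 cont_space):
        """Non-DLTs above xmin make H_n stochastically larger than H_0.

        Outcomes observed exactly at xmin are a special case: there
        π(xmin) = ρ0 identically, so under the independent uniform prior
        they inform only ρ0 and leave the MTD marginal untouched.
        """
        prior_cdf = compute_posterior([], uniform_prior, cont_space)
        at_xmin = compute_posterior([(140.0, 0)] * 5, uniform_prior,
                                    cont_space)
        g = np.linspace(141, 424, 50)
        assert at_xmin.cdf_at(g) == pytest.approx(prior_cdf.cdf_at(g),
                                                  abs=1e-9)
        post = compute_posterior([(200.0, 0)] * 5, uniform_prior, cont_space)
        assert np.all(post.cdf_at(g) <= prior_cdf.cdf_at(g) + 1e-12)
        assert post.quantile(0.5) > prior_cdf.quantile(0.5)

    def test_quantile_cdf_round_trip(self, uniform_prior, cont_space):
        post = compute_posterior([(140, 0), (226, 1)], uniform_prior,
                                 cont_space)
        for a in (0.1, 0.25, 0.5, 0.9):
            assert post.cdf_at(post.quantile(a)) == pytest.approx(a, abs=0.01)


class TestBivnormalPosterior:
    def test_extended_support_and_clipping(self, study_prior, cont_space):
        post = compute_posterior([], study_prior, cont_space)
        assert post.support == "extended"
        assert post.grid[0] < 140.0  # prior mass below the dose range
        assert mtd_quantile(post, 0.999, cont_space) == 425.0
        assert mtd_quantile(post, 0.001, cont_space) == 140.0

    def test_quantiles_stable_under_grid_refinement(self, study_prior,
                                                    cont_space):
        data = [(140, 0), (183, 0), (215, 1), (199, 0), (226, 1)]
        p400 = compute_posterior(data, study_prior, cont_space, resolution=400)
        p800 = compute_posterior(data, study_prior, cont_space, resolution=800)
        for a in (0.1, 0.25, 0.5):
            assert abs(p400.quantile(a) - p800.quantile(a)) < 0.5

    def test_matches_importance_sampling_oracle(self, study_prior,
                                                cont_space):
        """Quadrature quantiles agree with a 2×10⁵-draw MC oracle."""
        data = [(140, 0), (183, 0), (215, 1)]
        post = compute_posterior(data, study_prior, cont_space)
        rng = np.random.default_rng(11)
        from ewoc.posterior import _draw_beta

        b0, b1 = _draw_beta(study_prior, 200_000, rng)
        gam = (logit(THETA) - b0) / b1
        ll = np.zeros_like(b0)
        for d, y in data:
            eta = b0 + b1 * d
            ll += log_expit(eta) if y else log_expit(-eta)
        w = np.exp(ll - ll.max())
        order = np.argsort(gam)
        cw = np.cumsum(w[order])
        cw /= cw[-1]
        for a in (0.1, 0.25, 0.5):
            mc_q = gam[order][np.searchsorted(cw, a)]
            assert post.quantile(a) == pytest.approx(mc_q, abs=2.0)

    def test_dlt_observation_lowers_quantiles(self, study_prior, cont_space):
        eng = GridPosterior(study_prior, cont_space, resolution=201)
        base = eng.posterior([(140, 0), (200, 0)])
        worse = eng.posterior([(140, 0), (200, 0), (250, 1)])
        for a in (0.1, 0.25, 0.5):
            assert worse.quantile(a) <= base.quantile(a)

    def test_non_dlt_at_top_dose_never_decreases_quantiles(self, study_prior,
                                                           cont_space):
        """Stochastic ordering underlying coherent escalation."""
        eng = GridPosterior(study_prior, cont_space, resolution=201)
        data = [(140, 0), (190, 0), (240, 1), (215, 0)]
        before = eng.posterior(data)
        after = eng.posterior(data + [(240, 0)])
        for a in np.linspace(0.05, 0.95, 10):
            assert after.quantile(a) >= before.quantile(a) - 1e-9


class TestQuantileContract:
    def test_alpha_domain(self, uniform_prior, cont_space):
        post = compute_posterior([], uniform_prior, cont_space)
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                post.quantile(bad)


class TestPriorSummary:
    def test_study_prior_rho0_moments(self, study_prior):
        s = prior_summary(study_prior, xmin=140.0, theta=THETA,
                          n_draws=200_000, seed=5)
        assert s.rho0_mean == pytest.approx(0.203, abs=0.003)
        assert s.rho0_sd == pytest.approx(0.139, abs=0.003)

    def test_gamma_mean_matches_lognormal_closed_form(self, study_prior):
        closed = gamma_prior_mean_closed_form(study_prior, THETA)
        s = prior_summary(study_prior, n_draws=1_000_000, seed=5)
        se = s.gamma_sd / np.sqrt(s.n_draws)
        assert abs(s.gamma_mean - closed) < 4 * se

    def test_point_mass_prior_is_exact(self):
        prior = PriorSpec.bivariate_normal(sigma0=0.0, sigma1=0.0)
        s = prior_summary(prior, xmin=140.0, theta=THETA, n_draws=1000, seed=0)
        expected = expit(-2.56 + np.exp(-5.32) * 140.0)
        assert s.rho0_mean == pytest.approx(expected, abs=1e-12)
        assert s.rho0_sd == 0.0

    def test_uniform_prior_summary(self, uniform_prior):
        s = prior_summary(uniform_prior, n_draws=200_000, seed=2)
        assert s.gamma_mean == pytest.approx(282.5, abs=1.0)
        assert s.rho0_mean == pytest.approx(THETA / 2, abs=0.002)


class TestPriorSpecValidation:
    def test_bad_specs_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec.uniform(gamma_range=(425.0, 140.0))
        with pytest.raises(ValueError):
            PriorSpec.bivariate_normal(rho=1.0)
        with pytest.raises(ValueError):
            PriorSpec("no_such_family")

    def test_grid_backend_rejects_point_mass(self, cont_space):
        prior = PriorSpec.bivariate_normal(sigma0=0.0)
        with pytest.raises(ValueError):
            GridPosterior(prior, cont_space)


class TestMcmcBackend:
    """The ensemble-sampler backend agrees with the deterministic
    quadrature up to Monte-Carlo error (seed-to-seed quantile spread is a
    few mg/m² at these sampling settings)."""

    DATA = [(140, 0), (183, 0), (215, 1), (199, 0), (226, 1)]
    OPTS = dict(n_samples=40_000, burn_in=8_000, thin=2, chains=8)

    @pytest.mark.parametrize("prior_name", ["uniform", "bivnormal"])
    def test_agrees_with_grid_backend(self, prior_name, uniform_prior,
                                      study_prior, cont_space):
        from ewoc import compute_posterior_mcmc

        prior = uniform_prior if prior_name == "uniform" else study_prior
        grid = compute_posterior(self.DATA, prior, cont_space)
        mcmc = compute_posterior_mcmc(self.DATA, prior, cont_space, seed=3,
                                      **self.OPTS)
        for a in (0.1, 0.25, 0.5):
            assert mcmc.quantile(a) == pytest.approx(grid.quantile(a), abs=5.0)

    def test_seeded_sampler_reproducible(self, study_prior, cont_space):
        from ewoc import compute_posterior_mcmc

        opts = dict(n_samples=4_000, burn_in=2_000, thin=2, chains=4)
        a = compute_posterior_mcmc(self.DATA, study_prior, cont_space,
                                   seed=9, **opts)
        b = compute_posterior_mcmc(self.DATA, study_prior, cont_space,
                                   seed=9, **opts)
        assert np.array_equal(a.grid, b.grid)
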