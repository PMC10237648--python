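import math

import numpy as np
import pytest

from snapinfer.diagnostics import (bulk_probability_levels,
                                   effective_sample_size, kl_population,
                                   min_ess, population_density,
                                   population_grid, posterior_mean_density,
                                   predictive_band, prior_posterior_overlap,
                                   rhat, summary_statistic_trace)
from snapinfer.models import NormalComponent, PopulationModel, get_model
from snapinfer.priors import LogNormal


class TestESS:
    def test_iid_draws(self, rng):
        x = rng.standard_normal(10_000)
        assert effective_sample_size(x) == pytest.approx(10_000, rel=0.10)

    def test_ar1_closed_form(self, rng):
        n, rho = 100_000, 0.9
        innov = rng.standard_normal(n) * math.sqrt(1 - rho**2)
        x = np.empty(n)
        x[0] = innov[0]
        for i in range(1, n):
            x[i] = rho * x[i - 1] + innov[i]
        expected = n * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.15)

    def test_duplication_halves_ess_per_draw(self, rng):
        x = rng.standard_normal(4000)
        doubled = np.repeat(x, 2)
        ratio = effective_sample_size(doubled) / effective_sample_size(x)
        assert ratio == pytest.approx(1.0, rel=0.25)  # same ESS from 2n draws

    def test_constant_chain_is_nan(self):
        assert math.isnan(effective_sample_size(np.ones(500)))

    def test_min_ess(self, rng):
        draws = np.stack([rng.standard_normal(2000),
                          np.cumsum(rng.standard_normal(2000))], axis=1)
        assert min_ess(draws) == pytest.approx(
            effective_sample_size(draws[:, 1]))


class TestRhat:
    def test_identical_distributions(self, rng):
        chains = rng.standard_normal((4, 2000))
        assert rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_disjoint_means(self, rng):
        chains = rng.standard_normal((2, 500))
        chains[0] += 50.0
        assert rhat(chains) > 1.5

    def test_mixture_fixture(self, rng):
        good = rng.standard_normal((2, 1000))
        bad = good.copy()
        bad[0] += 2.0
        assert rhat(bad) > rhat(good)

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            rhat(rng.standard_normal((1, 100)))


class TestKLPopulation:
    def test_gaussian_closed_form(self):
        """Two unit-variance 1-D normals, means 0 and 1: KL = 0.5."""
        pop = PopulationModel([NormalComponent("x")])
        kl = kl_population(pop, np.array([0.0, 1.0]), np.array([[1.0, 1.0]]),
                           n_points=400)
        assert kl == pytest.approx(0.5, abs=1e-4)

    def test_posterior_at_truth_gives_zero(self):
        pop = PopulationModel([NormalComponent("x")])
        theta = np.array([2.0, 0.7])
        assert kl_population(pop, theta, theta[None, :]) == \
            pytest.approx(0.0, abs=1e-6)

    def test_nonnegative(self, rng):
        model = get_model("cancer")
        theta = np.array([10.0, 1.0, 2.0, 0.5, 0.8])
        samples = theta[None, :] + rng.normal(0, 0.05, size=(20, 5))
        assert kl_population(model.population, theta, samples,
                             n_points=80) >= 0.0

    def test_quadrature_matches_general_gaussian_formula(self):
        pop = PopulationModel([NormalComponent("x")])
        t_true = np.array([0.0, 1.0])
        t_post = np.array([[0.3, 1.5]])
        kl = kl_population(pop, t_true, t_post, n_points=400)
        mu0, s0, mu1, s1 = 0.0, 1.0, 0.3, 1.5
        closed = math.log(s1 / s0) + (s0**2 + (mu0 - mu1)**2) / (2 * s1**2) \
            - 0.5
        assert kl == pytest.approx(closed, abs=1e-4)

    def test_bulk_levels_monotone(self):
        pop = PopulationModel([NormalComponent("x")])
        pts, _, dv = population_grid(pop, np.array([0.0, 1.0]), 300)
        dens = population_density(pop, np.array([0.0, 1.0]), pts)
        levels = bulk_probability_levels(dens, dv)
        assert all(a > b for a, b in zip(levels, levels[1:]))


class TestPredictiveBand:
    def test_degenerate_posterior_zero_noise(self, rng):
        model = get_model("cancer")
        theta = np.array([10.0, 1e-9, 2.0, 1e-9, 1e-9])
        band = predictive_band(theta[None, :], model, [0.0, 0.3],
                               rng=rng, n_per_draw=50)
        ybar = 10.0 * np.exp(2.0 * np.array([0.0, 0.3]))
        for j in range(2):
            assert np.allclose(band[j, :, 0], ybar[j], rtol=1e-5)

    def test_pooled_variance_at_t0(self, rng):
        model = get_model("cancer")
        theta = np.array([10.0, 1.0, 2.0, 0.5, 0.8])
        band = predictive_band(theta[None, :], model, [0.0], rng=rng,
                               n_per_draw=40_000, percentiles=(5, 50, 95))
        # 5-95 band of N(10, 1.64): 10 +- 1.645*sqrt(1.64)
        half = 1.645 * math.sqrt(1.64)
        assert band[0, 0, 0] == pytest.approx(10 - half, abs=0.05)
        assert band[0, 2, 0] == pytest.approx(10 + half, abs=0.05)

    def test_quantiles_monotone(self, rng):
        model = get_model("cancer")
        theta = np.array([10.0, 1.0, 2.0, 0.5, 0.8])
        band = predictive_band(theta[None, :], model, [0.0, 0.6], rng=rng)
        assert np.all(np.diff(band[:, :, 0], axis=1) >= 0)


class TestSummaryStatisticTrace:
    def test_bookkeeping_identity(self, rng):
        y = rng.normal(10, 2, size=(7, 30, 6, 1))
        means, variances = summary_statistic_trace(y, time_index=5)
        assert np.allclose(means, y[:, :, 5, 0].mean(axis=1))
        assert np.allclose(variances, y[:, :, 5, 0].var(axis=1, ddof=1))

    def test_constant_chain_single_point(self, rng):
        y = np.tile(rng.normal(10, 2, size=(1, 30, 6, 1)), (5, 1, 1, 1))
        means, variances = summary_statistic_trace(y, 0)
        assert np.ptp(means) == 0 and np.ptp(variances) == 0

    def test_requires_stored_draws(self):
        with pytest.raises(ValueError):
            summary_statistic_trace(np.zeros((3, 4)), 0)


def test_prior_posterior_overlap_extremes(rng):
    prior = LogNormal(math.log(0.75), 0.2)
    close = np.exp(rng.normal(math.log(0.75), 0.2, size=4000))
    far = np.exp(rng.normal(math.log(20.0), 0.2, size=4000))
    assert prior_posterior_overlap(prior, close) > 0.9
    assert prior_posterior_overlap(prior, far) < 0.05


def test_posterior_mean_density_is_average(rng):
    pop = PopulationModel([NormalComponent("x")])
    pts = np.linspace(-4, 4, 50)[:, None]
    t1, t2 = np.array([0.0, 1.0]), np.array([1.0, 0.5])
    avg = posterior_mean_density(pop, np.stack([t1, t2]), pts)
    manual = 0.5 * (population_density(pop, t1, pts)
                    + population_density(pop, t2, pts))
    assert np.allclose(avg, manual)
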