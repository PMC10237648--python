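import math

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp
from scipy.stats import kstest, lognorm, norm

from snapinfer.models import (CancerGrowthModel, CovariateNormal, EGFRModel,
                              GaussianError, LogNormalComponent,
                              LogNormalError, NormalComponent, PointMass,
                              PopulationModel, get_model)

DG_EGF = np.array([1.7, 1.7, 8.0, 0.25, 0.015])  # data-generating rates


class TestCancerGrowth:
    @pytest.mark.parametrize("psi, t, expected", [
        ((10.0, 2.0), 0.0, 10.0),
        ((10.0, 0.0), 0.37, 10.0),
        ((10.0, 2.0), 0.6, 10.0 * math.exp(1.2)),
    ])
    def test_output(self, psi, t, expected):
        m = CancerGrowthModel()
        assert m.simulate(psi, [t])[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_sensitivities_match_finite_differences(self):
        m = CancerGrowthModel()
        psi = np.array([8.0, 1.5])
        times = np.linspace(0, 0.6, 4)
        _, sens = m.simulate_batch_with_sensitivities(psi[None], times)
        for k in range(2):
            dp = np.zeros(2)
            dp[k] = 1e-6
            fd = (m.simulate_batch(psi[None] + dp, times)
                  - m.simulate_batch(psi[None] - dp, times)) / 2e-6
            assert np.allclose(fd[0, :, 0], sens[0, :, 0, k], rtol=1e-5)

    def test_deterministic(self):
        m = CancerGrowthModel()
        a = m.simulate([3.0, 1.0], [0.1, 0.5])
        b = m.simulate([3.0, 1.0], [0.1, 0.5])
        assert np.array_equal(a, b)


class TestEGFR:
    def test_initial_condition_zero(self):
        m = EGFRModel(c_l=2.0)
        out = m.simulate(DG_EGF, [0.0])
        assert np.allclose(out, 0.0)

    def test_null_system(self):
        m = EGFRModel(c_l=0.0)
        out = m.simulate([0.0, 1.7, 8.0, 0.25, 0.015], [1.0, 10.0])
        assert np.allclose(out, 0.0)

    def test_steady_state_matches_linear_solve(self):
        m = EGFRModel(c_l=2.0)
        # independent oracle: solve A x = -b directly
        kon_cl = DG_EGF[1] * 2.0
        A = np.array([[-(kon_cl + DG_EGF[3]), DG_EGF[2]],
                      [kon_cl, -(DG_EGF[2] + DG_EGF[4])]])
        oracle = np.linalg.solve(A, [-DG_EGF[0], 0.0])
        assert oracle == pytest.approx([6.631, 2.813], abs=5e-4)
        assert m.simulate(DG_EGF, [500.0])[0] == pytest.approx(oracle,
                                                               rel=1e-8)

    def test_matches_generic_stiff_integrator(self):
        m = EGFRModel(c_l=10.0)
        psi = np.array([1.5, 2.0, 8.0, 0.25, 0.015])
        times = np.array([2.0, 10.0, 25.0])

        def rhs(t, x):
            p, kon, koff, kdr, kda = psi
            return [p - kon * 10.0 * x[0] + koff * x[1] - kdr * x[0],
                    kon * 10.0 * x[0] - koff * x[1] - kda * x[1]]

        sol = solve_ivp(rhs, (0, 25.0), [0.0, 0.0], t_eval=times,
                        method="LSODA", rtol=1e-10, atol=1e-12)
        assert np.allclose(m.simulate(psi, times), sol.y.T, rtol=1e-6)

    def test_sensitivities_match_finite_differences(self):
        m = EGFRModel(c_l=2.0)
        times = np.array([5.0, 25.0])
        _, sens = m.simulate_batch_with_sensitivities(DG_EGF[None], times)
        for k in range(5):
            dp = np.zeros(5)
            dp[k] = 1e-6 * max(DG_EGF[k], 1.0)
            fd = (m.simulate_batch(DG_EGF[None] + dp, times)
                  - m.simulate_batch(DG_EGF[None] - dp, times)) / (2 * dp[k])
            assert np.allclose(fd[0], sens[0, :, :, k], rtol=1e-4, atol=1e-10)

    def test_trajectories_nonnegative(self):
        m = EGFRModel(c_l=2.0)
        rng = np.random.default_rng(0)
        for _ in range(5):
            psi = rng.uniform(0, 5, size=5)
            out = m.simulate(psi, np.linspace(0, 25, 10))
            assert np.all(out >= -1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            EGFRModel(c_l=2.0).simulate([1.0, -1.0, 8.0, 0.25, 0.015], [1.0])


class TestErrorModels:
    def test_gaussian_at_mode(self):
        e = GaussianError()
        assert e.logpdf(5.0, 5.0, 1.0) == pytest.approx(
            -0.5 * math.log(2 * math.pi))

    def test_lognormal_at_median(self):
        e = LogNormalError()
        y, sigma = 3.0, 0.4
        expected = -math.log(y) - 0.5 * math.log(2 * math.pi * sigma**2)
        assert e.logpdf(y, y, sigma) == pytest.approx(expected, rel=1e-12)
        # cross-check the full density against scipy and unit normalisation
        assert e.logpdf(2.0, 3.0, 0.4) == pytest.approx(
            lognorm.logpdf(2.0, s=0.4, scale=3.0), rel=1e-12)
        mass, _ = quad(lambda v: math.exp(e.logpdf(v, 3.0, 0.4)), 1e-6, 100)
        assert mass == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("error, point", [
        (GaussianError(), (1.3, 1.0, 0.5)),
        (LogNormalError(), (1.3, 1.0, 0.5)),
    ])
    def test_gradients_match_finite_differences(self, error, point):
        y, ybar, sigma = point
        _, dy, dybar, dsigma = error.logpdf_grads(y, ybar, sigma)
        h = 1e-7
        for grad, idx in [(dy, 0), (dybar, 1), (dsigma, 2)]:
            args_p, args_m = list(point), list(point)
            args_p[idx] += h
            args_m[idx] -= h
            fd = (error.logpdf(*args_p) - error.logpdf(*args_m)) / (2 * h)
            assert float(grad) == pytest.approx(float(fd), rel=1e-6)

    def test_domain_violations_raise(self):
        with pytest.raises(ValueError):
            GaussianError().logpdf(1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            LogNormalError().logpdf(-1.0, 1.0, 0.5)


class TestPopulationModel:
    def test_point_mass_draws_exact(self, rng):
        model = get_model("cancer")
        theta = np.array([10.0, 1.0, 2.0, 0.5, 0.8])
        psi = model.population.sample(theta, 50, rng)
        assert np.all(psi[:, 2] == 0.8)

    def test_sample_mean_clt(self, rng):
        pop = PopulationModel([NormalComponent("lam")])
        n = 10**5
        draws = pop.sample([2.0, 0.5], n, rng)
        assert abs(draws.mean() - 2.0) < 3 * 0.5 / math.sqrt(n)

    def test_tiny_sd_allowed_zero_rejected(self, rng):
        pop = PopulationModel([NormalComponent("x")])
        draws = pop.sample([1.0, 1e-12], 10, rng)
        assert np.allclose(draws, 1.0)
        with pytest.raises(ValueError):
            pop.sample([1.0, 0.0], 10, rng)

    def test_logpdf_matches_scipy_product(self, rng):
        model = get_model("cancer")
        theta = np.array([10.0, 1.0, 2.0, 0.5, 0.8])
        psi = model.population.sample(theta, 20, rng)
        lp = model.population.logpdf(psi, theta)
        oracle = norm.logpdf(psi[:, 0], 10, 1) + norm.logpdf(psi[:, 1], 2, .5)
        assert np.allclose(lp, oracle, rtol=1e-12)

    def test_covariate_shifts_mean(self, rng):
        pop = PopulationModel([CovariateNormal("lam")])
        theta = [2.0, 2.0, 0.1]
        chi = np.concatenate([np.zeros(2000), np.ones(2000)])
        draws = pop.sample(theta, 4000, rng, chi)
        assert draws[:2000].mean() == pytest.approx(2.0, abs=0.02)
        assert draws[2000:].mean() == pytest.approx(4.0, abs=0.02)

    def test_lognormal_component_grads(self, rng):
        pop = PopulationModel([LogNormalComponent("k")])
        psi = np.array([[0.7], [1.9]])
        lp, dpsi, dtheta = pop.logpdf_grads(psi, [0.2, 0.5])
        assert np.allclose(lp, lognorm.logpdf(psi[:, 0], s=0.5,
                                              scale=math.exp(0.2)))
        h = 1e-7
        fd = (pop.logpdf(psi + h, [0.2, 0.5])
              - pop.logpdf(psi - h, [0.2, 0.5])) / (2 * h)
        assert np.allclose(dpsi[:, 0], fd, rtol=1e-6)

    def test_seeded_sampling_reproducible(self):
        pop = PopulationModel([NormalComponent("x"), PointMass("s")])
        a = pop.sample([0, 1, 2], 5, np.random.default_rng(3))
        b = pop.sample([0, 1, 2], 5, np.random.default_rng(3))
        assert np.array_equal(a, b)


def test_population_measurement_distribution_consistency(rng):
    """Monte-Carlo draws of noiseless cancer outputs converge (in KS
    distance) to p(y|theta,t) computed by 1-D quadrature."""
    model = get_model("cancer")
    theta = np.array([10.0, 1.0, 2.0, 0.5, 0.8])
    t = 0.3

    def cdf(y):
        # y = y0 * exp(lam * t); integrate over lam, conditioning y0
        def integrand(lam):
            return norm.pdf(lam, 2, 0.5) * norm.cdf(
                y / math.exp(lam * t), 10, 1)
        return quad(integrand, 2 - 8 * 0.5, 2 + 8 * 0.5)[0]

    distances = []
    for n in (200, 2000):
        psi = model.population.sample(theta, n, rng)
        y = psi[:, 0] * np.exp(psi[:, 1] * t)
        distances.append(kstest(y, np.vectorize(cdf)).statistic)
    assert distances[1] < distances[0]
    assert distances[1] < 0.05
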