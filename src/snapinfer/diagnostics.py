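"""Convergence and inference-quality diagnostics.

Includes autocorrelation-based effective sample size (Geyer's initial
monotone sequence estimator), rank-normalised split R-hat (via arviz), the
KL divergence between the data-generating population distribution and the
posterior-averaged inferred distribution E_{theta|D}[p(psi|theta)], posterior
predictive percentile bands, and the accepted-summary-statistic traces that
expose the implicit ABC error margin of summary-statistic filters.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "effective_sample_size", "min_ess", "rhat", "prior_posterior_overlap",
    "population_grid", "population_density", "posterior_mean_density",
    "kl_population", "bulk_probability_levels",
    "predictive_band", "summary_statistic_trace",
]


def effective_sample_size(draws) -> float:
    """ESS of a 1-D chain by Geyer's initial monotone sequence estimator.

    Returns ``nan`` for a constant chain (autocorrelation undefined).
    """
    x = np.asarray(draws, float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D chain; use min_ess for matrices")
    n = x.size
    if n < 4:
        raise ValueError("chain too short for an ESS estimate")
    x = x - x.mean()
    var0 = np.dot(x, x) / n
    if var0 == 0:
        return float("nan")
    # autocovariance via FFT
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    rho = acov / acov[0]
    # pair sums Gamma_k = rho_{2k} + rho_{2k+1}; truncate at first negative,
    # then enforce monotone non-increase
    n_pairs = (n - 1) // 2
    tau = 1.0  # rho_0
    prev = np.inf
    for k in range(n_pairs):
        pair = rho[2 * k + 1] + rho[2 * k + 2]
        if pair < 0:
            break
        pair = min(pair, prev)
        prev = pair
        tau += 2.0 * pair
    return float(n / tau)


def min_ess(draws) -> float:
    """Minimum ESS across the columns of an (iterations, dims) array."""
    draws = np.atleast_2d(np.asarray(draws, float))
    vals = [effective_sample_size(draws[:, k]) for k in range(draws.shape[1])]
    vals = [v for v in vals if np.isfinite(v)]
    return float(min(vals)) if vals else float("nan")


def rhat(chains) -> float:
    """Rank-normalised split R-hat across >= 2 equal-length chains."""
    import arviz as az

    chains = np.asarray(chains, float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length, shape "
                         "(n_chains, n_draws)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(az.convert_to_dataset(chains))["x"].item())


def prior_posterior_overlap(prior_dist, samples, n_grid=512) -> float:
    """Overlap coefficient between a 1-D prior and a posterior sample.

    integral of min(prior pdf, posterior KDE); 1 means the data did not
    update the prior at all (e.g. a noise scale that snapshot data cannot
    identify), 0 means disjoint.
    """
    from scipy.stats import gaussian_kde

    samples = np.asarray(samples, float)
    kde = gaussian_kde(samples)
    lo = min(samples.min(), np.quantile(samples, 0.005)) - 3 * samples.std()
    hi = samples.max() + 3 * samples.std()
    grid = np.linspace(lo, hi, n_grid)
    post = kde(grid)
    prior = np.exp([prior_dist.logpdf(g) for g in grid])
    return float(np.trapezoid(np.minimum(post, prior), grid))


# ---------------------------------------------------------------------------
# population-distribution comparisons


def population_grid(population, theta, n_points=120, n_sd=6.0):
    """Tensor grid over the free psi dimensions covering the bulk of
    p(psi | theta) (component mean +- n_sd standard deviations).

    Returns ``(points (n, n_free), axes, cell volume)``.
    """
    theta = np.asarray(theta, float)
    axes = []
    for k in population.free_psi_dims:
        comp = population.components[k]
        sl = population._slices[k]
        th = theta[sl]
        if comp.n_parameters == 2 and not comp.psi_positive:   # Normal
            lo, hi = th[0] - n_sd * th[1], th[0] + n_sd * th[1]
        elif comp.psi_positive:                                 # LogNormal
            lo = np.exp(th[0] - n_sd * th[1])
            hi = np.exp(th[0] + n_sd * th[1])
        else:                                                   # CovariateNormal
            sd = th[2]
            lo = min(th[0], th[0] + th[1]) - n_sd * sd
            hi = max(th[0], th[0] + th[1]) + n_sd * sd
        axes.append(np.linspace(lo, hi, n_points))
    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=1)
    dv = float(np.prod([ax[1] - ax[0] for ax in axes]))
    return points, axes, dv


def population_density(population, theta, points,
                       covariate_weights=None) -> np.ndarray:
    """p(psi | theta) on grid points over the free psi dimensions.

    For covariate-dependent populations the density is marginalised over the
    covariate (default: equal weights on chi = 0 and chi = 1).
    """
    theta = np.asarray(theta, float)
    points = np.atleast_2d(np.asarray(points, float))
    n = len(points)
    psi = np.zeros((n, population.n_psi))
    psi[:, population.free_psi_dims] = points
    psi = population.fill_point_masses(psi, theta)
    if population.requires_covariates():
        weights = covariate_weights or {0.0: 0.5, 1.0: 0.5}
        dens = np.zeros(n)
        for chi, w in weights.items():
            lp = population.logpdf(psi, theta, np.full(n, chi))
            dens += w * np.exp(lp)
        return dens
    return np.exp(population.logpdf(psi, theta))


def posterior_mean_density(population, theta_samples, points,
                           covariate_weights=None, thin_to=200) -> np.ndarray:
    """Pointwise posterior average E_{theta|D}[p(psi|theta)] on grid points."""
    theta_samples = np.atleast_2d(np.asarray(theta_samples, float))
    if len(theta_samples) > thin_to:
        idx = np.linspace(0, len(theta_samples) - 1, thin_to).astype(int)
        theta_samples = theta_samples[idx]
    dens = np.zeros(len(np.atleast_2d(points)))
    for theta in theta_samples:
        dens += population_density(population, theta, points,
                                   covariate_weights)
    return dens / len(theta_samples)


def kl_population(population, theta_true, theta_samples, n_points=120,
                  covariate_weights=None, thin_to=200) -> float:
    """KL(true population || posterior-averaged inferred population).

    Quadrature over a tensor grid covering the bulk of the true distribution;
    warns if the grid captures less than 99.9% of the true mass.
    """
    points, _, dv = population_grid(population, theta_true, n_points)
    q = population_density(population, theta_true, points, covariate_weights)
    mass = q.sum() * dv
    if mass < 0.999:
        warnings.warn(f"population grid covers only {mass:.4f} of the true "
                      "mass; enlarge n_sd/n_points")
    p = posterior_mean_density(population, theta_samples, points,
                               covariate_weights, thin_to)
    good = q > 0
    with np.errstate(divide="ignore"):
        integrand = np.where(good, q * (np.log(np.where(good, q, 1.0))
                                        - np.log(np.maximum(p, 1e-300))), 0.0)
    return float(integrand.sum() * dv)


def bulk_probability_levels(density, cell_volume, fractions=(0.2, 0.4, 0.6,
                                                             0.8)):
    """Density thresholds whose superlevel sets enclose the given mass."""
    dens = np.sort(np.asarray(density, float).ravel())[::-1]
    cum = np.cumsum(dens) * cell_volume
    total = cum[-1]
    levels = []
    for f in fractions:
        idx = np.searchsorted(cum, f * total)
        levels.append(float(dens[min(idx, len(dens) - 1)]))
    return levels


# ---------------------------------------------------------------------------
# predictive checks and filter-statistic traces


def predictive_band(theta_samples, model, times, percentiles=(5, 50, 95),
                    n_per_draw=100, rng=None, thin_to=200,
                    sim_covariates=None):
    """Percentiles of the posterior-averaged measurement distribution.

    For each (thinned) posterior draw, simulates ``n_per_draw`` individuals
    with measurement noise at every requested time, pools across draws, and
    takes per-time quantiles.  Returns an array (K, n_percentiles, n_obs).
    """
    rng = np.random.default_rng(rng)
    theta_samples = np.atleast_2d(np.asarray(theta_samples, float))
    if len(theta_samples) > thin_to:
        idx = np.linspace(0, len(theta_samples) - 1, thin_to).astype(int)
        theta_samples = theta_samples[idx]
    times = np.asarray(times, float)
    pop = model.population
    if sim_covariates is None and pop.requires_covariates():
        chi = np.zeros(n_per_draw)
        chi[n_per_draw // 2:] = 1.0
        sim_covariates = chi
    pooled = []
    for theta in theta_samples:
        psi = pop.sample(theta, n_per_draw, rng, sim_covariates)
        mech, sigma = model.split_psi(psi)
        ybar = model.time_series.simulate_batch(mech, times)
        pooled.append(model.error.sample(ybar, sigma[:, None, None], rng))
    pooled = np.concatenate(pooled, axis=0)          # (draws*n, K, n_obs)
    return np.percentile(pooled, percentiles, axis=0).transpose(1, 0, 2)


def summary_statistic_trace(y_draws, time_index, observable=0):
    """Accepted (mean, variance) pairs of simulated measurements per draw.

    ``y_draws`` is the (n_draws, S, K, n_obs) array returned by
    ``FilterPosterior.extract_simulated_measurements``; variance uses the
    S-1 denominator, matching the Gaussian filter statistics.
    """
    y_draws = np.asarray(y_draws, float)
    if y_draws.ndim != 4:
        raise ValueError("expected simulated-measurement draws of shape "
                         "(n_draws, S, K, n_obs); store Y~ draws to use this")
    col = y_draws[:, :, time_index, observable]
    return col.mean(axis=1), col.var(axis=1, ddof=1)
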