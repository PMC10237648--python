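"""NLME model building blocks and the concrete study models.

An NLME model bundles three parts:

* a deterministic time-series model ``ybar(psi, t)`` for the dynamics of one
  individual, with forward sensitivities ``d ybar / d psi``;
* an error model ``p(y | ybar, sigma)`` for measurement noise (Gaussian or
  lognormal with the model output as median);
* a population model ``p(psi | theta)`` describing inter-individual
  variability, built from independent per-dimension components (Normal,
  LogNormal, covariate-shifted Normal, or a point mass for parameters pooled
  across individuals).

The individual-level parameter vector ``psi`` consists of the mechanistic
parameters followed by the error-model scale ``sigma``.  Time-series models
carry an evaluation counter (one count per simulated individual trajectory)
used to verify the cost-scaling contracts of the inference routines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .priors import transform_for

_LOG_2PI = math.log(2.0 * math.pi)

__all__ = [
    "TimeSeriesModel", "CancerGrowthModel", "EGFRModel",
    "GaussianError", "LogNormalError",
    "NormalComponent", "LogNormalComponent", "PointMass", "CovariateNormal",
    "PopulationModel", "NLMEModel", "get_model",
]


# ---------------------------------------------------------------------------
# time-series models


class TimeSeriesModel:
    """Deterministic map from individual parameters and time to outputs."""

    n_parameters: int
    n_observables: int
    parameter_names: list

    def __init__(self):
        self.n_evaluations = 0  # one count per simulated individual

    def reset_counter(self):
        self.n_evaluations = 0

    def simulate(self, psi, times):
        """Outputs at ``times``; shape (K, n_observables)."""
        return self.simulate_batch(np.asarray(psi, float)[None, :], times)[0]

    def simulate_batch(self, psis, times):
        raise NotImplementedError

    def simulate_batch_with_sensitivities(self, psis, times, wrt=None):
        """Outputs (n, K, n_obs) and sensitivities (n, K, n_obs, len(wrt))."""
        raise NotImplementedError


class CancerGrowthModel(TimeSeriesModel):
    """Early exponential tumour growth, ``ybar(psi, t) = y0 * exp(lambda t)``."""

    n_parameters = 2
    n_observables = 1
    parameter_names = ["y0", "lambda"]
    observable_names = ["tumour_volume"]

    def simulate_batch(self, psis, times):
        psis = np.atleast_2d(np.asarray(psis, float))
        times = np.asarray(times, float)
        self.n_evaluations += len(psis)
        y0, lam = psis[:, 0], psis[:, 1]
        out = y0[:, None] * np.exp(lam[:, None] * times[None, :])
        return out[:, :, None]

    def simulate_batch_with_sensitivities(self, psis, times, wrt=None):
        psis = np.atleast_2d(np.asarray(psis, float))
        times = np.asarray(times, float)
        self.n_evaluations += len(psis)
        if wrt is None:
            wrt = [0, 1]
        y0, lam = psis[:, 0], psis[:, 1]
        growth = np.exp(lam[:, None] * times[None, :])        # (n, K)
        out = (y0[:, None] * growth)[:, :, None]
        sens = np.empty((len(psis), len(times), 1, len(wrt)))
        for a, k in enumerate(wrt):
            if k == 0:
                sens[:, :, 0, a] = growth
            elif k == 1:
                sens[:, :, 0, a] = y0[:, None] * times[None, :] * growth
            else:
                raise IndexError(f"no parameter with index {k}")
        return out, sens


class EGFRModel(TimeSeriesModel):
    """Inactive/active EGF receptor concentrations under constant EGF.

    States (both observables, initialised at 0 ng/mL):

    * ``c_r`` — inactive receptor, produced at rate ``p``, activated at rate
      ``kon * c_l``, replenished by deactivation ``koff``, degraded at
      ``kdeg_r``;
    * ``c_a`` — active receptor, deactivating at ``koff`` and degrading at
      ``kdeg_a``.

    The system is linear time-invariant, so trajectories and forward
    sensitivities are computed exactly with a matrix exponential of an
    augmented system (states, sensitivities, and a constant-input dimension).
    """

    n_parameters = 5
    n_observables = 2
    parameter_names = ["p", "kon", "koff", "kdeg_r", "kdeg_a"]
    observable_names = ["c_r", "c_a"]

    def __init__(self, c_l: float):
        super().__init__()
        if c_l < 0:
            raise ValueError("EGF concentration must be non-negative")
        self.c_l = float(c_l)

    def _system(self, psi):
        p, kon, koff, kdr, kda = psi
        A = np.array([[-(kon * self.c_l + kdr), koff],
                      [kon * self.c_l, -(koff + kda)]])
        b = np.array([p, 0.0])
        return A, b

    def _dA(self, k):
        cl = self.c_l
        if k == 1:    # kon
            return np.array([[-cl, 0.0], [cl, 0.0]])
        if k == 2:    # koff
            return np.array([[0.0, 1.0], [0.0, -1.0]])
        if k == 3:    # kdeg_r
            return np.array([[-1.0, 0.0], [0.0, 0.0]])
        if k == 4:    # kdeg_a
            return np.array([[0.0, 0.0], [0.0, -1.0]])
        return np.zeros((2, 2))  # p enters through b only

    def _db(self, k):
        return np.array([1.0, 0.0]) if k == 0 else np.zeros(2)

    def simulate_batch(self, psis, times):
        out, _ = self._solve(psis, times, wrt=[])
        return out

    def simulate_batch_with_sensitivities(self, psis, times, wrt=None):
        if wrt is None:
            wrt = list(range(self.n_parameters))
        return self._solve(psis, times, wrt=list(wrt))

    def _solve(self, psis, times, wrt):
        psis = np.atleast_2d(np.asarray(psis, float))
        times = np.asarray(times, float)
        if np.any(psis[:, 1:] < 0):
            raise ValueError("EGFR rate constants must be non-negative")
        n = len(psis)
        self.n_evaluations += n
        q = len(wrt)
        d = 2 * (q + 1) + 1
        # augmented generator: d/dt (x, s_1..s_q, 1) is linear and homogeneous
        M = np.zeros((n, d, d))
        for c, psi in enumerate(psis):
            A, b = self._system(psi)
            M[c, 0:2, 0:2] = A
            M[c, 0:2, -1] = b
            for a, k in enumerate(wrt):
                r = 2 + 2 * a
                M[c, r:r + 2, 0:2] = self._dA(k)
                M[c, r:r + 2, r:r + 2] = A
                M[c, r:r + 2, -1] = self._db(k)
        # batch over (individual, time); z(t) = expm(M t) e_last
        Mt = M[:, None, :, :] * times[None, :, None, None]
        try:
            Z = expm(Mt.reshape(n * len(times), d, d))
        except Exception as err:  # pragma: no cover - defensive
            raise RuntimeError(f"EGFR trajectory solve failed: {err}") from err
        z = Z[:, :, -1].reshape(n, len(times), d)
        if not np.all(np.isfinite(z)):
            raise RuntimeError("EGFR trajectory solve produced non-finite values")
        out = z[:, :, 0:2]
        if not wrt:
            return out, None
        sens = np.empty((n, len(times), 2, q))
        for a in range(q):
            sens[:, :, :, a] = z[:, :, 2 + 2 * a:4 + 2 * a]
        return out, sens

    def steady_state(self, psi):
        """Exact steady state, ``-A^{-1} b``."""
        A, b = self._system(np.asarray(psi, float))
        return np.linalg.solve(-A, b)


# ---------------------------------------------------------------------------
# error models


class GaussianError:
    """Additive Gaussian noise, ``y ~ N(ybar, sigma^2)``."""

    name = "gaussian"
    positive_outputs = False

    def logpdf(self, y, ybar, sigma):
        y, ybar, sigma = np.broadcast_arrays(
            np.asarray(y, float), np.asarray(ybar, float), np.asarray(sigma, float))
        if np.any(sigma <= 0):
            raise ValueError("sigma must be positive")
        z = (y - ybar) / sigma
        return -0.5 * _LOG_2PI - np.log(sigma) - 0.5 * z * z

    def logpdf_grads(self, y, ybar, sigma):
        """Log-density plus derivatives w.r.t. (y, ybar, sigma)."""
        y, ybar, sigma = np.broadcast_arrays(
            np.asarray(y, float), np.asarray(ybar, float), np.asarray(sigma, float))
        if np.any(sigma <= 0):
            raise ValueError("sigma must be positive")
        var = sigma**2
        resid = y - ybar
        lp = -0.5 * _LOG_2PI - np.log(sigma) - 0.5 * resid**2 / var
        dy = -resid / var
        dsigma = -1.0 / sigma + resid**2 / (var * sigma)
        return lp, dy, -dy, dsigma

    def in_support(self, y, ybar):
        return np.isfinite(np.asarray(y, float))

    def sample(self, ybar, sigma, rng):
        ybar = np.asarray(ybar, float)
        return ybar + sigma * rng.standard_normal(ybar.shape)


class LogNormalError:
    """Multiplicative lognormal noise with the model output as median.

    ``ln y ~ N(ln ybar, sigma^2)``; requires strictly positive ``y``/``ybar``.
    """

    name = "lognormal"
    positive_outputs = True

    def logpdf(self, y, ybar, sigma):
        y, ybar, sigma = np.broadcast_arrays(
            np.asarray(y, float), np.asarray(ybar, float), np.asarray(sigma, float))
        if np.any(sigma <= 0):
            raise ValueError("sigma must be positive")
        if np.any(y <= 0) or np.any(ybar <= 0):
            raise ValueError("lognormal error requires positive y and ybar")
        z = (np.log(y) - np.log(ybar)) / sigma
        return -np.log(y) - np.log(sigma) - 0.5 * _LOG_2PI - 0.5 * z * z

    def logpdf_grads(self, y, ybar, sigma):
        y, ybar, sigma = np.broadcast_arrays(
            np.asarray(y, float), np.asarray(ybar, float), np.asarray(sigma, float))
        if np.any(sigma <= 0):
            raise ValueError("sigma must be positive")
        if np.any(y <= 0) or np.any(ybar <= 0):
            raise ValueError("lognormal error requires positive y and ybar")
        var = sigma**2
        z = np.log(y) - np.log(ybar)
        lp = -np.log(y) - np.log(sigma) - 0.5 * _LOG_2PI - 0.5 * z**2 / var
        dy = (-1.0 - z / var) / y
        dybar = z / (var * ybar)
        dsigma = -1.0 / sigma + z**2 / (var * sigma)
        return lp, dy, dybar, dsigma

    def in_support(self, y, ybar):
        return (np.asarray(y, float) > 0) & (np.asarray(ybar, float) > 0)

    def sample(self, ybar, sigma, rng):
        ybar = np.asarray(ybar, float)
        if np.any(ybar <= 0):
            raise ValueError(
                "lognormal error model is undefined for non-positive model "
                "outputs; check times/parameters producing zero concentrations")
        return ybar * np.exp(sigma * rng.standard_normal(ybar.shape))


# ---------------------------------------------------------------------------
# population model components (independent per psi dimension)


class NormalComponent:
    """psi_k ~ N(mu, sd^2); theta slice is (mu, sd)."""

    n_parameters = 2
    is_point_mass = False
    psi_positive = False

    def __init__(self, name):
        self.name = name
        self.parameter_names = [f"mu_{name}", f"sigma_{name}"]
        self.positive = [False, True]

    def _check(self, theta):
        if theta[1] <= 0:
            raise ValueError(f"sigma_{self.name} must be positive")

    def sample(self, theta, n, rng, covariates=None):
        self._check(theta)
        return rng.normal(theta[0], theta[1], size=n)

    def logpdf_grads(self, psi_k, theta, covariates=None):
        self._check(theta)
        mu, sd = theta
        z = (psi_k - mu) / sd
        lp = -0.5 * _LOG_2PI - math.log(sd) - 0.5 * z * z
        dpsi = -z / sd
        dtheta = np.stack([z / sd, (z * z - 1.0) / sd], axis=-1)
        return lp, dpsi, dtheta

    def standard_to_natural(self, theta, eta, covariates=None):
        """psi from standard-normal innovations, with partials.

        Returns ``(psi, dpsi/deta, dpsi/dtheta (n, n_parameters))``.
        """
        self._check(theta)
        mu, sd = theta
        psi = mu + sd * eta
        return psi, np.full_like(eta, sd), \
            np.stack([np.ones_like(eta), eta], axis=-1)

    def natural_to_standard(self, theta, psi_k, covariates=None):
        self._check(theta)
        return (psi_k - theta[0]) / theta[1]


class LogNormalComponent:
    """psi_k ~ LogNormal(location, scale); theta slice is (location, scale)."""

    n_parameters = 2
    is_point_mass = False
    psi_positive = True

    def __init__(self, name):
        self.name = name
        self.parameter_names = [f"loc_{name}", f"scale_{name}"]
        self.positive = [False, True]

    def _check(self, theta):
        if theta[1] <= 0:
            raise ValueError(f"scale_{self.name} must be positive")

    def sample(self, theta, n, rng, covariates=None):
        self._check(theta)
        return np.exp(rng.normal(theta[0], theta[1], size=n))

    def logpdf_grads(self, psi_k, theta, covariates=None):
        self._check(theta)
        loc, scale = theta
        if np.any(psi_k <= 0):
            raise ValueError(f"{self.name} must be positive under a lognormal "
                             "population component")
        z = (np.log(psi_k) - loc) / scale
        lp = -np.log(psi_k) - math.log(scale) - 0.5 * _LOG_2PI - 0.5 * z * z
        dpsi = (-1.0 - z / scale) / psi_k
        dtheta = np.stack([z / scale, (z * z - 1.0) / scale], axis=-1)
        return lp, dpsi, dtheta

    def standard_to_natural(self, theta, eta, covariates=None):
        self._check(theta)
        loc, scale = theta
        psi = np.exp(loc + scale * eta)
        return psi, psi * scale, np.stack([psi, psi * eta], axis=-1)

    def natural_to_standard(self, theta, psi_k, covariates=None):
        self._check(theta)
        if np.any(psi_k <= 0):
            raise ValueError(f"{self.name} must be positive")
        return (np.log(psi_k) - theta[0]) / theta[1]


class PointMass:
    """Parameter pooled across individuals: psi_k = theta value exactly.

    Contributes 0 to the population log-density and is never a free sampling
    dimension at the individual level; gradients w.r.t. the theta value flow
    through wherever psi_k is used (e.g. the error model).
    """

    n_parameters = 1
    is_point_mass = True
    psi_positive = False

    def __init__(self, name, positive=True):
        self.name = name
        self.parameter_names = [f"mu_{name}"]
        self.positive = [positive]

    def sample(self, theta, n, rng, covariates=None):
        return np.full(n, theta[0])

    def logpdf_grads(self, psi_k, theta, covariates=None):
        zero = np.zeros_like(np.asarray(psi_k, float))
        return zero, zero, zero[..., None]


class CovariateNormal:
    """psi_k ~ N(mu_base + chi * delta, sd^2) with binary covariate chi.

    theta slice is (mu_base, delta, sd); models e.g. a moderate/aggressive
    disease variant shifting the mean growth rate.
    """

    n_parameters = 3
    is_point_mass = False
    psi_positive = False

    def __init__(self, name):
        self.name = name
        self.parameter_names = [f"mu_{name}_base", f"delta_mu_{name}",
                                f"sigma_{name}"]
        self.positive = [False, False, True]

    def _check(self, theta):
        if theta[2] <= 0:
            raise ValueError(f"sigma_{self.name} must be positive")

    def _mean(self, theta, covariates, n):
        if covariates is None:
            raise ValueError(f"component {self.name} requires covariates")
        chi = np.asarray(covariates, float)
        if chi.shape[0] != n:
            raise ValueError("covariate length mismatch")
        return theta[0] + chi * theta[1], chi

    def sample(self, theta, n, rng, covariates=None):
        self._check(theta)
        mean, _ = self._mean(theta, covariates, n)
        return rng.normal(mean, theta[2])

    def logpdf_grads(self, psi_k, theta, covariates=None):
        self._check(theta)
        psi_k = np.asarray(psi_k, float)
        mean, chi = self._mean(theta, covariates, len(psi_k))
        sd = theta[2]
        z = (psi_k - mean) / sd
        lp = -0.5 * _LOG_2PI - math.log(sd) - 0.5 * z * z
        dpsi = -z / sd
        dtheta = np.stack([z / sd, chi * z / sd, (z * z - 1.0) / sd], axis=-1)
        return lp, dpsi, dtheta

    def standard_to_natural(self, theta, eta, covariates=None):
        self._check(theta)
        mean, chi = self._mean(theta, covariates, len(eta))
        psi = mean + theta[2] * eta
        return psi, np.full_like(eta, theta[2]), \
            np.stack([np.ones_like(eta), chi, eta], axis=-1)

    def natural_to_standard(self, theta, psi_k, covariates=None):
        self._check(theta)
        mean, _ = self._mean(theta, covariates, len(psi_k))
        return (psi_k - mean) / theta[2]


class PopulationModel:
    """Product of independent per-dimension components, ``p(psi | theta)``."""

    def __init__(self, components):
        self.components = list(components)
        self.n_psi = len(self.components)
        self.theta_names = []
        self.theta_positive = []
        self._slices = []
        start = 0
        for comp in self.components:
            self.theta_names.extend(comp.parameter_names)
            self.theta_positive.extend(comp.positive)
            self._slices.append(slice(start, start + comp.n_parameters))
            start += comp.n_parameters
        self.n_theta = start
        self.free_psi_dims = [k for k, c in enumerate(self.components)
                              if not c.is_point_mass]
        self.point_mass_map = [
            (k, self._slices[k].start)
            for k, c in enumerate(self.components) if c.is_point_mass
        ]
        self.psi_names = [c.name for c in self.components]

    def requires_covariates(self) -> bool:
        return any(isinstance(c, CovariateNormal) for c in self.components)

    def sample(self, theta, n, rng, covariates=None):
        """n i.i.d. draws of the full psi vector; shape (n, n_psi)."""
        theta = np.asarray(theta, float)
        psi = np.empty((n, self.n_psi))
        for k, comp in enumerate(self.components):
            psi[:, k] = comp.sample(theta[self._slices[k]], n, rng, covariates)
        return psi

    def logpdf(self, psi, theta, covariates=None):
        lp, _, _ = self.logpdf_grads(psi, theta, covariates)
        return lp

    def logpdf_grads(self, psi, theta, covariates=None):
        """Per-individual log-density with gradients.

        Returns ``(lp (n,), dpsi (n, n_psi), dtheta (n, n_theta))``; point-mass
        dimensions contribute zero everywhere (their constraint is enforced by
        construction, not by a density).
        """
        psi = np.atleast_2d(np.asarray(psi, float))
        theta = np.asarray(theta, float)
        n = len(psi)
        lp = np.zeros(n)
        dpsi = np.zeros((n, self.n_psi))
        dtheta = np.zeros((n, self.n_theta))
        for k, comp in enumerate(self.components):
            lpk, dpsik, dthetak = comp.logpdf_grads(
                psi[:, k], theta[self._slices[k]], covariates)
            lp += lpk
            dpsi[:, k] = dpsik
            dtheta[:, self._slices[k]] = dthetak
        return lp, dpsi, dtheta

    def fill_point_masses(self, psi, theta):
        """Overwrite point-mass psi dimensions with their theta values."""
        psi = np.array(psi, float, copy=True)
        for k, j in self.point_mass_map:
            psi[..., k] = theta[j]
        return psi

    def theta_transforms(self):
        return [transform_for(p) for p in self.theta_positive]

    def psi_transforms(self):
        return [transform_for(self.components[k].psi_positive)
                for k in self.free_psi_dims]


# ---------------------------------------------------------------------------
# model bundle and registry


@dataclass
class NLMEModel:
    """Bundle of time-series model, error model and population model.

    ``psi = (mechanistic parameters..., sigma)``; the population model must
    have one component per psi dimension, in that order.
    """

    time_series: TimeSeriesModel
    error: object
    population: PopulationModel
    name: str = "model"

    def __post_init__(self):
        if self.population.n_psi != self.time_series.n_parameters + 1:
            raise ValueError(
                "population model must cover mechanistic parameters plus sigma")

    @property
    def n_mech(self):
        return self.time_series.n_parameters

    @property
    def theta_names(self):
        return self.population.theta_names

    def split_psi(self, psi):
        """(mechanistic part, sigma) of a (n, n_psi) psi array."""
        psi = np.atleast_2d(psi)
        return psi[:, : self.n_mech], psi[:, self.n_mech]


def observable_map(ts_model, observables):
    """Map dataset observable names to time-series model output indices."""
    observables = list(observables)
    if len(observables) == 1 and ts_model.n_observables == 1:
        return {observables[0]: 0}
    names = ts_model.observable_names
    missing = [o for o in observables if o not in names]
    if missing:
        raise KeyError(f"dataset observables {missing} not produced by "
                       f"{type(ts_model).__name__} (outputs: {names})")
    return {o: names.index(o) for o in observables}


_EGF_FIXED = {"koff": 8.0, "kdeg_r": 0.25, "kdeg_a": 0.015}


def get_model(name: str, **kwargs) -> NLMEModel:
    """Model registry: ``cancer``, ``egf`` (kwarg ``c_l``), ``cancer-bimodal``."""
    if name == "cancer":
        pop = PopulationModel([
            NormalComponent("y0"), NormalComponent("lambda"),
            PointMass("sigma"),
        ])
        return NLMEModel(CancerGrowthModel(), GaussianError(), pop, name)
    if name == "cancer-bimodal":
        pop = PopulationModel([
            NormalComponent("y0"), CovariateNormal("lambda"),
            PointMass("sigma"),
        ])
        return NLMEModel(CancerGrowthModel(), GaussianError(), pop, name)
    if name == "egf":
        c_l = kwargs.pop("c_l", 2.0)
        pop = PopulationModel([
            NormalComponent("p"), NormalComponent("kon"),
            PointMass("koff"), PointMass("kdeg_r"), PointMass("kdeg_a"),
            PointMass("sigma"),
        ])
        return NLMEModel(EGFRModel(c_l), LogNormalError(), pop, name)
    raise KeyError(f"unknown model {name!r}")
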