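"""Prior distributions and parameter transforms.

Priors are specified on the natural parameter scale as a mapping from
population-parameter name to a 1-D distribution.  Samplers work on an
unconstrained scale; positive parameters (standard deviations, rates, noise
scales) are mapped through ``log`` with the appropriate Jacobian correction,
so model code always sees natural-scale values.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Normal", "LogNormal", "Uniform", "Flat", "PriorSpec",
    "IdentityTransform", "LogTransform", "transform_for",
]

_LOG_2PI = math.log(2.0 * math.pi)


class Normal:
    def __init__(self, mean: float, sd: float):
        if sd <= 0:
            raise ValueError("sd must be positive")
        self.mean, self.sd = float(mean), float(sd)

    def logpdf(self, x):
        z = (x - self.mean) / self.sd
        return -0.5 * _LOG_2PI - math.log(self.sd) - 0.5 * z * z

    def dlogpdf(self, x):
        return -(x - self.mean) / self.sd**2

    def sample(self, rng):
        return rng.normal(self.mean, self.sd)

    def in_support(self, x):
        return np.isfinite(x)


class LogNormal:
    """Lognormal with location/scale on the log scale (median ``exp(location)``)."""

    def __init__(self, location: float, scale: float):
        if scale <= 0:
            raise ValueError("scale must be positive")
        self.location, self.scale = float(location), float(scale)

    def logpdf(self, x):
        if x <= 0:
            return -np.inf
        z = (math.log(x) - self.location) / self.scale
        return -math.log(x) - math.log(self.scale) - 0.5 * _LOG_2PI - 0.5 * z * z

    def dlogpdf(self, x):
        z = (math.log(x) - self.location) / self.scale
        return (-1.0 - z / self.scale) / x

    def sample(self, rng):
        return math.exp(rng.normal(self.location, self.scale))

    def in_support(self, x):
        return x > 0


class Uniform:
    def __init__(self, low: float, high: float):
        if not high > low:
            raise ValueError("high must exceed low")
        self.low, self.high = float(low), float(high)

    def logpdf(self, x):
        if self.low <= x <= self.high:
            return -math.log(self.high - self.low)
        return -np.inf

    def dlogpdf(self, x):
        return 0.0

    def sample(self, rng):
        return rng.uniform(self.low, self.high)

    def in_support(self, x):
        return self.low <= x <= self.high


class Flat:
    """Improper flat prior on the natural scale (log-density 0 everywhere)."""

    def __init__(self, positive: bool = False):
        self.positive = positive

    def logpdf(self, x):
        if self.positive and x <= 0:
            return -np.inf
        return 0.0

    def dlogpdf(self, x):
        return 0.0

    def sample(self, rng):
        raise RuntimeError("cannot sample from an improper flat prior")

    def in_support(self, x):
        return (x > 0) if self.positive else np.isfinite(x)


class PriorSpec:
    """Independent priors over named population parameters.

    Parameters absent from the mapping and not declared fixed raise at
    construction of a posterior, so mis-spelled names fail loudly.
    """

    def __init__(self, priors: dict):
        self.priors = dict(priors)

    def __contains__(self, name):
        return name in self.priors

    def __getitem__(self, name):
        return self.priors[name]

    def logpdf(self, names, values) -> float:
        total = 0.0
        for name, value in zip(names, values):
            total += self.priors[name].logpdf(value)
            if not np.isfinite(total):
                return -np.inf
        return total

    def dlogpdf(self, names, values) -> np.ndarray:
        return np.array(
            [self.priors[n].dlogpdf(v) for n, v in zip(names, values)]
        )

    def sample(self, names, rng) -> np.ndarray:
        return np.array([self.priors[n].sample(rng) for n in names])


# ---------------------------------------------------------------------------
# transforms between unconstrained sampler space and natural parameter space


class IdentityTransform:
    name = "identity"

    def to_natural(self, x):
        return x

    def to_unconstrained(self, u):
        return u

    def dnatural(self, x):
        """d(natural)/d(unconstrained) evaluated at unconstrained x."""
        return np.ones_like(np.asarray(x, float))

    def log_jacobian(self, x):
        return np.zeros_like(np.asarray(x, float))

    def dlog_jacobian(self, x):
        return np.zeros_like(np.asarray(x, float))


class LogTransform:
    """natural = exp(unconstrained); keeps positive parameters unconstrained."""

    name = "log"

    def to_natural(self, x):
        return np.exp(x)

    def to_unconstrained(self, u):
        u = np.asarray(u, float)
        if np.any(u <= 0):
            raise ValueError("log transform requires positive values")
        return np.log(u)

    def dnatural(self, x):
        return np.exp(x)

    def log_jacobian(self, x):
        return np.asarray(x, float)

    def dlog_jacobian(self, x):
        return np.ones_like(np.asarray(x, float))


IDENTITY = IdentityTransform()
LOG = LogTransform()


def transform_for(positive: bool):
    return LOG if positive else IDENTITY
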