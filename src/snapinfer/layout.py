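"""Mapping between unconstrained sampler vectors and natural parameters."""

from __future__ import annotations

import numpy as np

__all__ = ["ThetaLayout", "TransformedBlock"]


class TransformedBlock:
    """A block of parameters with per-dimension transforms."""

    def __init__(self, transforms):
        self.transforms = list(transforms)
        self.n = len(self.transforms)

    def to_natural(self, x):
        x = np.asarray(x, float)
        return np.array([t.to_natural(v) for t, v in zip(self.transforms, x)])

    def to_unconstrained(self, u):
        u = np.asarray(u, float)
        return np.array([t.to_unconstrained(v)
                         for t, v in zip(self.transforms, u)])

    def dnatural(self, x):
        return np.array([t.dnatural(v) for t, v in zip(self.transforms, x)])

    def log_jacobian(self, x):
        return float(sum(t.log_jacobian(v)
                         for t, v in zip(self.transforms, x)))

    def dlog_jacobian(self, x):
        return np.array([t.dlog_jacobian(v)
                         for t, v in zip(self.transforms, x)])


class ThetaLayout:
    """Free/fixed split of the population parameter vector theta.

    ``fixed`` maps parameter names to values excluded from sampling (e.g. a
    noise scale pinned to its data-generating value).
    """

    def __init__(self, population, fixed=None):
        self.population = population
        self.fixed = dict(fixed or {})
        names = population.theta_names
        unknown = set(self.fixed) - set(names)
        if unknown:
            raise KeyError(f"fixed parameters {sorted(unknown)} not in theta "
                           f"({names})")
        self.all_names = list(names)
        self.free_idx = np.array(
            [i for i, n in enumerate(names) if n not in self.fixed], dtype=int)
        self.free_names = [names[i] for i in self.free_idx]
        all_transforms = population.theta_transforms()
        self.block = TransformedBlock([all_transforms[i] for i in self.free_idx])
        self.n_free = len(self.free_idx)

    def full_theta(self, free_natural):
        theta = np.empty(len(self.all_names))
        for name, value in self.fixed.items():
            theta[self.all_names.index(name)] = value
        theta[self.free_idx] = free_natural
        return theta

    def to_natural(self, x_free):
        """Unconstrained free block -> full natural theta."""
        return self.full_theta(self.block.to_natural(x_free))

    def to_unconstrained(self, theta_full):
        return self.block.to_unconstrained(
            np.asarray(theta_full, float)[self.free_idx])

    def free_of(self, theta_full):
        return np.asarray(theta_full, float)[self.free_idx]
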