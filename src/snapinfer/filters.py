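"""Population filters: approximate measurement densities built from simulations.

A filter turns the ``S`` simulated measurements at one (time point,
observable) into a parametric density ``p(y | Y~_j)`` that stands in for the
intractable population measurement distribution.  Five families are provided:

* ``gaussian`` — normal with the empirical mean and variance (S-1 denominator)
  of the simulated measurements;
* ``lognormal`` — lognormal with location/scale from the log-transformed
  simulations;
* ``gaussian_mixture`` — M equally weighted normal kernels, the m-th fitted to
  the m-th contiguous block of S/M simulated individuals;
* ``gaussian_kde`` — kernel density estimate with one kernel per simulated
  measurement and the rule-of-thumb bandwidth ``b^2 = (4/(3S))^{2/5} var``;
* ``lognormal_kde`` — the same construction on the log scale.

Every filter exposes the log-density and its gradients with respect to both
the evaluation point and every simulated measurement (including the
dependence through the empirical statistics and the bandwidth), which is what
makes the deterministic filter posterior differentiable end to end.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import logsumexp, softmax

_LOG_2PI = math.log(2.0 * math.pi)

__all__ = [
    "GaussianFilter", "LognormalFilter", "GaussianMixtureFilter",
    "GaussianKDEFilter", "LognormalKDEFilter",
    "kde_bandwidth", "build_filter", "FILTER_FAMILIES",
]


def kde_bandwidth(sims, log_domain: bool = False) -> float:
    """Rule-of-thumb squared bandwidth ``b^2 = (4/(3S))^{2/5} * var``.

    ``var`` is the empirical variance (S-1 denominator) of the simulated
    measurements, of their logs when ``log_domain``.
    """
    sims = np.asarray(sims, float)
    S = sims.size
    if S < 2:
        raise ValueError("bandwidth rule requires at least two simulations")
    if log_domain:
        if np.any(sims <= 0):
            raise ValueError("log-domain bandwidth requires positive values")
        sims = np.log(sims)
    var = sims.var(ddof=1)
    if var <= 0:
        raise ValueError("simulated measurements have zero variance")
    return (4.0 / (3.0 * S)) ** 0.4 * var


def _check_sims(sims, positive=False):
    sims = np.asarray(sims, float)
    if sims.ndim != 1 or sims.size < 2:
        raise ValueError("filter construction requires a 1-D array with S >= 2")
    if not np.all(np.isfinite(sims)):
        raise ValueError("simulated measurements must be finite")
    if positive and np.any(sims <= 0):
        raise ValueError("this filter requires strictly positive simulations")
    return sims


def _scalar_aware(y, out):
    return float(out[0]) if np.asarray(y).ndim == 0 else out


class _Filter:
    """Common interface; subclasses fill in the three core methods."""

    def logpdf(self, y):
        raise NotImplementedError

    def logpdf_grads(self, y):
        """Return ``(logpdf (n,), d/dy (n,), d/dsims (n, S))``."""
        raise NotImplementedError

    def in_support(self, y):
        return np.isfinite(np.asarray(y, float))


class GaussianFilter(_Filter):
    """Normal density with the empirical mean/variance of the simulations."""

    family = "gaussian"

    def __init__(self, sims):
        sims = _check_sims(sims)
        self.sims = sims
        self.S = sims.size
        self.mean = sims.mean()
        self.var = sims.var(ddof=1)
        if self.var <= 0:
            raise ValueError("simulated measurements have zero variance")

    def logpdf(self, y):
        y = np.asarray(y, float)
        return -0.5 * (_LOG_2PI + np.log(self.var)) \
            - 0.5 * (y - self.mean) ** 2 / self.var

    def logpdf_grads(self, y):
        y = np.atleast_1d(np.asarray(y, float))
        resid = y - self.mean
        lp = -0.5 * (_LOG_2PI + np.log(self.var)) - 0.5 * resid**2 / self.var
        dy = -resid / self.var
        dmean = resid / self.var
        dvar = -0.5 / self.var + 0.5 * resid**2 / self.var**2
        # dmean/ds = 1/S, dvar/ds_u = 2 (s_u - mean) / (S - 1)
        dsims = dmean[:, None] / self.S + dvar[:, None] * (
            2.0 * (self.sims - self.mean) / (self.S - 1))[None, :]
        return lp, dy, dsims


class LognormalFilter(_Filter):
    """Lognormal with location/scale from the log-transformed simulations."""

    family = "lognormal"

    def __init__(self, sims):
        sims = _check_sims(sims, positive=True)
        self.sims = sims
        self._inner = GaussianFilter(np.log(sims))

    def in_support(self, y):
        return np.asarray(y, float) > 0

    def logpdf(self, y):
        y = np.asarray(y, float)
        if np.any(y <= 0):
            raise ValueError("lognormal filter requires positive y")
        return self._inner.logpdf(np.log(y)) - np.log(y)

    def logpdf_grads(self, y):
        y = np.atleast_1d(np.asarray(y, float))
        if np.any(y <= 0):
            raise ValueError("lognormal filter requires positive y")
        lp, dly, dlsims = self._inner.logpdf_grads(np.log(y))
        lp = lp - np.log(y)
        dy = (dly - 1.0) / y
        dsims = dlsims / self.sims[None, :]
        return lp, dy, dsims


class GaussianMixtureFilter(_Filter):
    """Equally weighted normal kernels fitted to contiguous simulation blocks.

    When simulated individuals carry a covariate, callers should order them by
    covariate so that kernels can align with subpopulations.
    """

    family = "gaussian_mixture"

    def __init__(self, sims, n_kernels: int):
        sims = _check_sims(sims)
        M = int(n_kernels)
        if M < 1:
            raise ValueError("need at least one kernel")
        if sims.size % M != 0:
            raise ValueError(f"S={sims.size} not divisible by M={M}")
        if sims.size // M < 2:
            raise ValueError(
                "need S/M >= 2 simulations per kernel (for the KDE limit use "
                "the dedicated KDE filters, which carry their own bandwidth)")
        self.sims = sims
        self.S = sims.size
        self.M = M
        self.B = sims.size // M
        blocks = sims.reshape(M, self.B)
        self.means = blocks.mean(axis=1)
        self.vars = blocks.var(axis=1, ddof=1)
        if np.any(self.vars <= 0):
            raise ValueError("a simulation block has zero variance")

    def _component_logpdfs(self, y):
        resid = y[:, None] - self.means[None, :]
        return -0.5 * (_LOG_2PI + np.log(self.vars))[None, :] \
            - 0.5 * resid**2 / self.vars[None, :]

    def logpdf(self, y):
        out = logsumexp(self._component_logpdfs(
            np.atleast_1d(np.asarray(y, float))), axis=1) - math.log(self.M)
        return _scalar_aware(y, out)

    def logpdf_grads(self, y):
        y = np.atleast_1d(np.asarray(y, float))
        comp = self._component_logpdfs(y)                      # (n, M)
        lp = logsumexp(comp, axis=1) - math.log(self.M)
        resp = softmax(comp, axis=1)                           # (n, M)
        resid = y[:, None] - self.means[None, :]
        dcomp_dy = -resid / self.vars[None, :]
        dy = (resp * dcomp_dy).sum(axis=1)
        dmean = resp * (resid / self.vars[None, :])            # (n, M)
        dvar = resp * (-0.5 / self.vars[None, :]
                       + 0.5 * resid**2 / self.vars[None, :] ** 2)
        blocks = self.sims.reshape(self.M, self.B)
        dstat = 2.0 * (blocks - self.means[:, None]) / (self.B - 1)  # (M, B)
        dsims = (dmean[:, :, None] / self.B
                 + dvar[:, :, None] * dstat[None, :, :])
        return lp, dy, dsims.reshape(len(y), self.S)


class GaussianKDEFilter(_Filter):
    """Gaussian KDE with the rule-of-thumb bandwidth.

    By default the bandwidth is treated as a function of the simulations, so
    gradients include its dependence on them; ``freeze_bandwidth`` drops those
    terms.
    """

    family = "gaussian_kde"

    def __init__(self, sims, freeze_bandwidth: bool = False):
        sims = _check_sims(sims)
        self.sims = sims
        self.S = sims.size
        self.mean = sims.mean()
        self.bw2 = kde_bandwidth(sims)
        self._bw_factor = (4.0 / (3.0 * self.S)) ** 0.4
        self.freeze_bandwidth = freeze_bandwidth

    def _kernel_logpdfs(self, y):
        resid = y[:, None] - self.sims[None, :]
        return -0.5 * (_LOG_2PI + math.log(self.bw2)) \
            - 0.5 * resid**2 / self.bw2

    def logpdf(self, y):
        out = logsumexp(self._kernel_logpdfs(
            np.atleast_1d(np.asarray(y, float))), axis=1) - math.log(self.S)
        return _scalar_aware(y, out)

    def logpdf_grads(self, y):
        y = np.atleast_1d(np.asarray(y, float))
        kern = self._kernel_logpdfs(y)                         # (n, S)
        lp = logsumexp(kern, axis=1) - math.log(self.S)
        resp = softmax(kern, axis=1)
        resid = y[:, None] - self.sims[None, :]
        dy = (resp * (-resid / self.bw2)).sum(axis=1)
        # direct kernel-centre term
        dsims = resp * (resid / self.bw2)
        if not self.freeze_bandwidth:
            dlp_dbw2 = (resp * (-0.5 / self.bw2
                                + 0.5 * resid**2 / self.bw2**2)).sum(axis=1)
            dbw2_dsims = self._bw_factor * 2.0 * (self.sims - self.mean) \
                / (self.S - 1)
            dsims = dsims + dlp_dbw2[:, None] * dbw2_dsims[None, :]
        return lp, dy, dsims


class LognormalKDEFilter(_Filter):
    """Lognormal kernels centred on the simulated measurements.

    Equivalent to a Gaussian KDE on the log scale (bandwidth from the
    log-variance) minus ``ln y``.
    """

    family = "lognormal_kde"

    def __init__(self, sims, freeze_bandwidth: bool = False):
        sims = _check_sims(sims, positive=True)
        self.sims = sims
        self._inner = GaussianKDEFilter(np.log(sims),
                                        freeze_bandwidth=freeze_bandwidth)
        self.bw2 = self._inner.bw2

    def in_support(self, y):
        return np.asarray(y, float) > 0

    def logpdf(self, y):
        if np.any(np.asarray(y, float) <= 0):
            raise ValueError("lognormal KDE filter requires positive y")
        y1 = np.atleast_1d(np.asarray(y, float))
        return _scalar_aware(y, self._inner.logpdf(np.log(y1)) - np.log(y1))

    def logpdf_grads(self, y):
        y = np.atleast_1d(np.asarray(y, float))
        if np.any(y <= 0):
            raise ValueError("lognormal KDE filter requires positive y")
        lp, dly, dlsims = self._inner.logpdf_grads(np.log(y))
        return lp - np.log(y), (dly - 1.0) / y, dlsims / self.sims[None, :]


FILTER_FAMILIES = {
    "gaussian": GaussianFilter,
    "lognormal": LognormalFilter,
    "gaussian_mixture": GaussianMixtureFilter,
    "gaussian_kde": GaussianKDEFilter,
    "lognormal_kde": LognormalKDEFilter,
}


def build_filter(family: str, sims, **options) -> _Filter:
    """Construct a filter by family name.

    Options: ``n_kernels`` (gaussian_mixture, required), ``freeze_bandwidth``
    (KDE families).
    """
    try:
        cls = FILTER_FAMILIES[family]
    except KeyError:
        raise KeyError(f"unknown filter family {family!r}; choose from "
                       f"{sorted(FILTER_FAMILIES)}") from None
    return cls(sims, **options)
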