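"""MCMC engines: random-walk Metropolis-Hastings and a No-U-Turn sampler.

Both samplers operate on a simple contract: MH needs a callable
``target(x) -> log-density``; NUTS needs ``target(x) -> (log-density,
gradient)``.  Positions live on an unconstrained scale — posterior objects in
this package handle constraint transforms and Jacobians internally.

Every sampler counts its target evaluations; for NUTS each evaluation
includes the gradient, so the two counters coincide.  Seeded runs are exactly
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ChainResult", "mh_sample", "nuts_sample"]


@dataclass
class ChainResult:
    """MCMC draws with bookkeeping.

    ``draws`` includes warmup iterations; ``samples`` strips them.
    """

    draws: np.ndarray
    parameter_names: list
    n_warmup: int
    acceptance_rate: float
    n_evaluations: int
    n_gradient_evaluations: int
    seed: object = None
    divergences: int = 0
    step_size: float | None = None
    sampler: str = "mh"
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_warmup > len(self.draws):
            raise ValueError("warmup cannot exceed the number of draws")

    @property
    def samples(self) -> np.ndarray:
        return self.draws[self.n_warmup:]

    def to_dataframe(self, include_warmup=False) -> pd.DataFrame:
        data = self.draws if include_warmup else self.samples
        return pd.DataFrame(data, columns=self.parameter_names)

    def manifest(self) -> dict:
        return {
            "sampler": self.sampler,
            "n_iterations": int(len(self.draws)),
            "n_warmup": int(self.n_warmup),
            "acceptance_rate": float(self.acceptance_rate),
            "n_evaluations": int(self.n_evaluations),
            "n_gradient_evaluations": int(self.n_gradient_evaluations),
            "divergences": int(self.divergences),
            "step_size": None if self.step_size is None else float(self.step_size),
            "seed": self.seed,
            "parameter_names": list(self.parameter_names),
            **self.extras,
        }

    def save(self, prefix) -> None:
        """Write ``<prefix>.csv`` (all draws) and ``<prefix>.json`` manifest."""
        pd.DataFrame(self.draws, columns=self.parameter_names).to_csv(
            f"{prefix}.csv", index=False, float_format="%.17g")
        with open(f"{prefix}.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=1)

    @classmethod
    def load(cls, prefix) -> "ChainResult":
        df = pd.read_csv(f"{prefix}.csv", float_precision="round_trip")
        with open(f"{prefix}.json") as fh:
            man = json.load(fh)
        return cls(
            draws=df.to_numpy(float),
            parameter_names=man["parameter_names"],
            n_warmup=man["n_warmup"],
            acceptance_rate=man["acceptance_rate"],
            n_evaluations=man["n_evaluations"],
            n_gradient_evaluations=man["n_gradient_evaluations"],
            seed=man.get("seed"),
            divergences=man.get("divergences", 0),
            step_size=man.get("step_size"),
            sampler=man.get("sampler", "mh"),
        )


def mh_sample(target, x0, n_iterations, scales=1.0, seed=None, n_warmup=0,
              adapt=None, target_acceptance=0.234,
              parameter_names=None) -> ChainResult:
    """Gaussian random-walk Metropolis-Hastings with component-wise scales.

    Parameters
    ----------
    target
        Callable returning the log-density (may be ``-inf``; a stochastic
        target re-estimated per call is allowed).
    scales
        Scalar or per-dimension proposal standard deviations.
    adapt
        ``None`` (fixed scales), ``"global"`` (one multiplicative factor tuned
        to ``target_acceptance`` during warmup) or ``"diag"`` (additionally
        per-dimension scales proportional to the running chain standard
        deviations).
    """
    rng = np.random.default_rng(seed)
    x = np.atleast_1d(np.asarray(x0, float)).copy()
    d = x.size
    scales = np.broadcast_to(np.asarray(scales, float), (d,)).copy()
    if np.any(scales < 0):
        raise ValueError("proposal scales must be non-negative")
    score = float(target(x))
    if not np.isfinite(score):
        raise ValueError("target is not finite at the starting point")
    n_eval = 1
    draws = np.empty((n_iterations, d))
    log_factor = 0.0
    accepted_total = 0
    # running moments for diagonal adaptation
    mean = x.copy()
    m2 = np.zeros(d)
    for i in range(n_iterations):
        step = scales * np.exp(log_factor)
        proposal = x + step * rng.standard_normal(d)
        score_new = float(target(proposal))
        n_eval += 1
        accept = np.log(rng.uniform()) < score_new - score
        if accept:
            x, score = proposal, score_new
            accepted_total += 1
        draws[i] = x
        if adapt is not None and i < n_warmup:
            eta = (i + 1) ** -0.6
            log_factor += eta * ((1.0 if accept else 0.0) - target_acceptance)
            if adapt == "diag":
                delta = x - mean
                mean += delta / (i + 2)
                m2 += delta * (x - mean)
                if i >= max(10, n_warmup // 10) and (i + 1) % 50 == 0:
                    sd = np.sqrt(m2 / (i + 1))
                    if np.any(sd > 0):
                        sd = np.where(sd > 0, sd, np.median(sd[sd > 0]))
                        scales = sd
    names = parameter_names or [f"x{k}" for k in range(d)]
    return ChainResult(
        draws=draws, parameter_names=names, n_warmup=n_warmup,
        acceptance_rate=accepted_total / n_iterations,
        n_evaluations=n_eval, n_gradient_evaluations=0, seed=seed,
        sampler="mh", extras={"final_scale_factor": float(np.exp(log_factor))})


class _DualAveraging:
    """Nesterov dual averaging of the log step size (Hoffman & Gelman)."""

    def __init__(self, eps0, target_accept, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target_accept
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_prob):
        self.count += 1
        frac = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        w = self.count ** -self.kappa
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar

    @property
    def eps(self):
        return float(np.exp(self.log_eps))

    @property
    def eps_final(self):
        return float(np.exp(self.log_eps_bar))


def nuts_sample(target, x0, n_warmup=500, n_main=1000, seed=None,
                target_accept=0.8, max_depth=10, m_inv=None,
                adapt_mass=True, parameter_names=None) -> ChainResult:
    """Adaptive No-U-Turn sampler.

    Warmup adapts the step size by dual averaging throughout and estimates a
    diagonal inverse mass matrix from an inner window of warmup draws.
    Divergent trajectories are counted, not fatal.

    Parameters
    ----------
    target
        Callable ``x -> (log-density, gradient)``.
    m_inv
        Optional initial diagonal inverse mass (per-dimension posterior
        variance guess).
    """
    rng = np.random.default_rng(seed)
    x = np.atleast_1d(np.asarray(x0, float)).copy()
    d = x.size
    m_inv = np.ones(d) if m_inv is None else \
        np.broadcast_to(np.asarray(m_inv, float), (d,)).copy()
    if np.any(m_inv <= 0):
        raise ValueError("inverse mass entries must be positive")
    counters = {"n": 0}

    def ev(pos):
        counters["n"] += 1
        lp, grad = target(pos)
        return float(lp), np.asarray(grad, float)

    lp, grad = ev(x)
    if not np.isfinite(lp):
        raise ValueError("target is not finite at the starting point")

    def leapfrog(pos, mom, g, eps):
        mom = mom + 0.5 * eps * g
        pos = pos + eps * m_inv * mom
        lp_new, g_new = ev(pos)
        if not np.isfinite(lp_new):
            return pos, mom, lp_new, g_new, -np.inf
        mom = mom + 0.5 * eps * g_new
        joint = lp_new - 0.5 * np.sum(mom * mom * m_inv)
        return pos, mom, lp_new, g_new, joint

    def joint_of(lp_val, mom):
        return lp_val - 0.5 * np.sum(mom * mom * m_inv)

    # -- reasonable initial step size (double/halve heuristic)
    eps = 0.1 * float(np.min(np.sqrt(m_inv))) if d > 1 else 1.0
    mom0 = rng.standard_normal(d) / np.sqrt(m_inv)
    j0 = joint_of(lp, mom0)
    _, _, _, _, j1 = leapfrog(x, mom0, grad, eps)
    direction = 1.0 if (j1 - j0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        _, _, _, _, j1 = leapfrog(x, mom0, grad, eps)
        if direction * (j1 - j0) < direction * np.log(0.5):
            break
    da = _DualAveraging(eps, target_accept)

    DIVERGENCE = 1000.0

    def build_tree(pos, mom, g, logu, v, depth, eps, joint0):
        """Recursive tree doubling (slice-sampling variant)."""
        if depth == 0:
            pos1, mom1, lp1, g1, joint = leapfrog(pos, mom, g, v * eps)
            n_valid = int(logu <= joint)
            divergent = (logu - DIVERGENCE) > joint
            alpha = min(1.0, np.exp(min(0.0, joint - joint0)))
            return (pos1, mom1, g1, pos1, mom1, g1, pos1, n_valid,
                    not divergent, alpha, 1, divergent)
        (xm, pm, gm, xp, pp, gp, xprop, n_valid, cont, alpha, n_alpha,
         div) = build_tree(pos, mom, g, logu, v, depth - 1, eps, joint0)
        if cont:
            if v == -1:
                (xm, pm, gm, _, _, _, xprop2, n2, cont2, a2, na2,
                 div2) = build_tree(xm, pm, gm, logu, v, depth - 1, eps, joint0)
            else:
                (_, _, _, xp, pp, gp, xprop2, n2, cont2, a2, na2,
                 div2) = build_tree(xp, pp, gp, logu, v, depth - 1, eps, joint0)
            if n2 > 0 and rng.uniform() < n2 / max(n_valid + n2, 1):
                xprop = xprop2
            n_valid += n2
            alpha += a2
            n_alpha += na2
            div = div or div2
            dx = xp - xm
            cont = cont2 and np.dot(dx, m_inv * pm) >= 0 \
                and np.dot(dx, m_inv * pp) >= 0
        return (xm, pm, gm, xp, pp, gp, xprop, n_valid, cont, alpha,
                n_alpha, div)

    n_total = n_warmup + n_main
    draws = np.empty((n_total, d))
    divergences = 0
    accept_stats = []
    # mass adaptation window (inner slice of warmup)
    win_lo, win_hi = int(0.15 * n_warmup), int(0.85 * n_warmup)
    wmean = np.zeros(d)
    wm2 = np.zeros(d)
    wcount = 0

    eps = da.eps
    for i in range(n_total):
        mom = rng.standard_normal(d) / np.sqrt(m_inv)
        joint0 = joint_of(lp, mom)
        logu = joint0 + np.log(rng.uniform())
        xm = xp = x
        pm = pp = mom
        gm = gp = grad
        n_valid = 1
        cont = True
        depth = 0
        alpha_sum, n_alpha = 0.0, 0
        x_new, lp_new, grad_new = x, lp, grad
        while cont and depth < max_depth:
            v = 1 if rng.uniform() < 0.5 else -1
            if v == -1:
                (xm, pm, gm, _, _, _, xprop, n2, cont2, a2, na2,
                 div) = build_tree(xm, pm, gm, logu, v, depth, eps, joint0)
            else:
                (_, _, _, xp, pp, gp, xprop, n2, cont2, a2, na2,
                 div) = build_tree(xp, pp, gp, logu, v, depth, eps, joint0)
            if div:
                divergences += 1
            if cont2 and n2 > 0 and rng.uniform() < min(1.0, n2 / n_valid):
                x_new = xprop
            n_valid += n2
            alpha_sum += a2
            n_alpha += na2
            dx = xp - xm
            cont = cont2 and np.dot(dx, m_inv * pm) >= 0 \
                and np.dot(dx, m_inv * pp) >= 0
            depth += 1
        if not np.array_equal(x_new, x):
            lp_new, grad_new = ev(x_new)
        x, lp, grad = x_new, lp_new, grad_new
        draws[i] = x
        accept_prob = alpha_sum / max(n_alpha, 1)
        accept_stats.append(accept_prob)
        if i < n_warmup:
            da.update(accept_prob)
            eps = da.eps
            if adapt_mass and win_lo <= i < win_hi:
                wcount += 1
                delta = x - wmean
                wmean += delta / wcount
                wm2 += delta * (x - wmean)
            if i == win_hi - 1 and wcount > 10:
                var = wm2 / max(wcount - 1, 1)
                # regularise towards unity like Stan does
                m_inv = (wcount / (wcount + 5.0)) * var \
                    + 1e-3 * (5.0 / (wcount + 5.0))
                m_inv = np.maximum(m_inv, 1e-10)
                da = _DualAveraging(eps, target_accept)
        elif i == n_warmup:
            eps = da.eps_final if da.count > 0 else eps
    names = parameter_names or [f"x{k}" for k in range(d)]
    return ChainResult(
        draws=draws, parameter_names=names, n_warmup=n_warmup,
        acceptance_rate=float(np.mean(accept_stats[n_warmup:]
                                      if n_main else accept_stats)),
        n_evaluations=counters["n"], n_gradient_evaluations=counters["n"],
        seed=seed, divergences=divergences, step_size=float(eps),
        sampler="nuts")
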