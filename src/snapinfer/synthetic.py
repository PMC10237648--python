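"""Seeded generators for the three synthetic study designs.

All three designs are snapshot designs: every individual is measured exactly
once, at a time point assigned deterministically in blocks.

* ``generate_cancer`` — early exponential tumour growth with additive
  Gaussian noise; 15 individuals per time point at 6 evenly spaced times on
  [0, 0.6] (including 0), scaled by an integer multiplier, with
  theta = (mu_y0, sigma_y0, mu_lambda, sigma_lambda, mu_sigma)
        = (10, 1, 2, 0.5, 0.8).
* ``generate_egf`` — EGF receptor activation at a constant EGF concentration
  (2 or 10 ng/mL); 1200 cells over 25 min, each snapshot measuring both
  receptor concentrations with lognormal noise (scale 0.05), population
  parameters (1.7, 0.05, 1.7, 0.05) for (p, kon) and pooled
  (koff, kdeg_r, kdeg_a, sigma) = (8, 0.25, 0.015, 0.05).
* ``generate_bimodal_cancer`` — two cancer variants: a moderate and an
  aggressive subpopulation whose mean growth rate is shifted by
  delta_mu_lambda = 2, half of the individuals each, balanced within every
  time point; (10, 1, 2, 2, 0.5, 0.8).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import SnapshotDataset
from .models import get_model

__all__ = [
    "CANCER_THETA", "EGF_THETA", "BIMODAL_THETA",
    "CANCER_TIMES", "egf_times",
    "generate_cancer", "generate_egf", "generate_bimodal_cancer",
]

CANCER_THETA = np.array([10.0, 1.0, 2.0, 0.5, 0.8])
EGF_THETA = np.array([1.7, 0.05, 1.7, 0.05, 8.0, 0.25, 0.015, 0.05])
BIMODAL_THETA = np.array([10.0, 1.0, 2.0, 2.0, 0.5, 0.8])

CANCER_TIMES = np.linspace(0.0, 0.6, 6)


def egf_times(K: int = 6) -> np.ndarray:
    """K evenly spaced times on (0, 25] min (t=0 excluded: zero initial
    concentrations make the lognormal error undefined there)."""
    return 25.0 * np.arange(1, K + 1) / K


def _snapshot(model, theta, times, n_per_time, rng, covariates_per_time=None,
              observables=None, id_width=None):
    """Blockwise snapshot sampling: one measurement (set) per individual."""
    pop = model.population
    total = n_per_time * len(times)
    id_width = id_width or len(str(total))
    ids, t_col, obs_col, val_col, chi_col = [], [], [], [], []
    next_id = 1
    for j, t in enumerate(times):
        chi = None if covariates_per_time is None else covariates_per_time[j]
        psi = pop.sample(theta, n_per_time, rng, chi)
        mech, sigma = model.split_psi(psi)
        ybar = model.time_series.simulate_batch(mech, np.array([t]))
        y = model.error.sample(ybar, sigma[:, None, None], rng)  # (n, 1, n_obs)
        names = observables or model.time_series.observable_names
        for i in range(n_per_time):
            id_ = f"{next_id:0{id_width}d}"
            next_id += 1
            for o, obs in enumerate(names):
                ids.append(id_)
                t_col.append(t)
                obs_col.append(obs)
                val_col.append(y[i, 0, o])
                if chi is not None:
                    chi_col.append(chi[i])
    df = pd.DataFrame({"ID": ids, "Time": t_col, "Observable": obs_col,
                       "Value": val_col})
    if covariates_per_time is not None:
        df["Covariate"] = chi_col
    return SnapshotDataset(df)


def generate_cancer(scale: int = 1, seed=None,
                    n_per_time: int | None = None) -> SnapshotDataset:
    """Cancer growth snapshots: 15 * scale individuals per time point.

    ``scale`` in {1, 3, 9, 27} reproduces the study's N = 90, 270, 810, 2430;
    ``n_per_time`` overrides the per-time-point count for custom designs.
    """
    if int(scale) != scale or scale < 1:
        raise ValueError("scale must be a positive integer")
    if n_per_time is None:
        n_per_time = 15 * int(scale)
    rng = np.random.default_rng(seed)
    model = get_model("cancer")
    return _snapshot(model, CANCER_THETA, CANCER_TIMES, n_per_time, rng)


def generate_egf(c_l: float = 2.0, n_cells: int = 1200, K: int = 6,
                 seed=None) -> SnapshotDataset:
    """EGF receptor snapshots: both observables per cell, lognormal noise."""
    if n_cells % K != 0:
        raise ValueError(f"n_cells={n_cells} must be divisible by K={K}")
    rng = np.random.default_rng(seed)
    model = get_model("egf", c_l=c_l)
    return _snapshot(model, EGF_THETA, egf_times(K), n_cells // K, rng)


def generate_bimodal_cancer(n_total: int = 120, seed=None) -> SnapshotDataset:
    """Two-variant cancer growth with a recorded binary covariate.

    Half the individuals carry the aggressive variant (chi = 1), balanced
    within each time point to avoid confounding time with variant.
    """
    K = len(CANCER_TIMES)
    if n_total % (2 * K) != 0:
        raise ValueError(f"n_total={n_total} must be divisible by {2 * K}")
    rng = np.random.default_rng(seed)
    model = get_model("cancer-bimodal")
    n_per_time = n_total // K
    chi = np.zeros(n_per_time)
    chi[n_per_time // 2:] = 1.0
    covs = [chi] * K
    return _snapshot(model, BIMODAL_THETA, CANCER_TIMES, n_per_time, rng,
                     covariates_per_time=covs)
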