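"""Scripted, seeded study designs tying all modules together.

Each experiment generates its synthetic dataset, runs the requested
inference(s), and returns chains plus a manifest that fully determines a
rerun.  Default sampler budgets are scaled down (200 warmup + 300 main NUTS
iterations, one chain) so a study completes on a desk machine; pass
``full_budget=True`` for 500 + 1000 iterations.
"""

from __future__ import annotations

import math

import numpy as np

from . import diagnostics as diag
from .filter_inference import FilterPosterior
from .hierarchical import HierarchicalPosterior
from .models import get_model
from .priors import LogNormal, Normal, PriorSpec
from .samplers import nuts_sample
from .synthetic import (BIMODAL_THETA, CANCER_THETA, EGF_THETA,
                        generate_bimodal_cancer, generate_cancer,
                        generate_egf)

__all__ = [
    "default_cancer_prior", "default_bimodal_prior", "default_egf_prior",
    "run_cancer_comparison", "run_egf", "run_filter_bias_study",
    "run_S_sweep",
]


def default_cancer_prior() -> PriorSpec:
    """Weakly informative priors covering the cancer data-generating values.

    The noise prior concentrates on scales between roughly 0.5 and 1, since
    snapshot data cannot separate noise from initial-volume variability.
    """
    return PriorSpec({
        "mu_y0": Normal(9.0, 3.0),
        "sigma_y0": LogNormal(0.0, 0.5),
        "mu_lambda": Normal(1.5, 1.5),
        "sigma_lambda": LogNormal(math.log(0.5), 0.5),
        "mu_sigma": LogNormal(math.log(0.75), 0.2),
    })


def default_bimodal_prior() -> PriorSpec:
    """Priors for the two-variant cancer model.

    The variant shift ``delta_mu_lambda`` gets a positive (lognormal) prior,
    which also pins the labelling of the two subpopulations.
    """
    return PriorSpec({
        "mu_y0": Normal(9.0, 3.0),
        "sigma_y0": LogNormal(0.0, 0.5),
        "mu_lambda_base": Normal(1.5, 1.5),
        "delta_mu_lambda": LogNormal(0.0, 0.75),
        "sigma_lambda": LogNormal(math.log(0.5), 0.5),
        "mu_sigma": LogNormal(math.log(0.75), 0.2),
    })


def default_egf_prior() -> PriorSpec:
    """Priors for the EGF receptor model (free parameters only)."""
    return PriorSpec({
        "mu_p": Normal(1.5, 0.5),
        "sigma_p": LogNormal(math.log(0.05), 0.5),
        "mu_kon": Normal(1.5, 0.5),
        "sigma_kon": LogNormal(math.log(0.05), 0.5),
        "mu_koff": LogNormal(math.log(6.0), 0.5),
    })


def _budget(full_budget, n_warmup, n_main):
    if n_warmup is None:
        n_warmup = 500 if full_budget else 200
    if n_main is None:
        n_main = 1000 if full_budget else 300
    return n_warmup, n_main


def _run_nuts(posterior, seed, n_warmup, n_main, theta0=None, **nuts_kwargs):
    rng = np.random.default_rng(seed)
    x0 = posterior.initialize_state(rng, theta=theta0) \
        if hasattr(posterior, "initialize_state") \
        else posterior.sample_initial(rng, theta=theta0)
    m_inv = nuts_kwargs.pop("m_inv", None)
    if m_inv is None and hasattr(posterior, "initial_scales"):
        m_inv = posterior.initial_scales() ** 2
    chain = nuts_sample(posterior.evaluate, x0, n_warmup=n_warmup,
                        n_main=n_main, seed=seed, m_inv=m_inv,
                        parameter_names=posterior.parameter_names,
                        **nuts_kwargs)
    return chain


def _theta_summaries(theta_samples, names):
    means = theta_samples.mean(axis=0)
    lo, hi = np.percentile(theta_samples, [5, 95], axis=0)
    return {
        name: {"mean": float(means[k]), "ci90": [float(lo[k]), float(hi[k])]}
        for k, name in enumerate(names)
    }


def run_cancer_comparison(scale=1, S=100, seed=1, n_warmup=None, n_main=None,
                          full_budget=False, run_traditional=None,
                          compute_kl=True, nuts_kwargs=None):
    """Filter inference vs traditional NLME on the cancer growth design.

    Traditional NLME runs by default only at ``scale=1`` (N=90), where it is
    still cheap; filter inference runs at every scale.
    """
    n_warmup, n_main = _budget(full_budget, n_warmup, n_main)
    if run_traditional is None:
        run_traditional = scale == 1
    nuts_kwargs = nuts_kwargs or {}
    data = generate_cancer(scale, seed=seed)
    prior = default_cancer_prior()
    model = get_model("cancer")
    posterior = FilterPosterior(data, model, prior, S=S,
                                filter_family="gaussian")
    chain = _run_nuts(posterior, seed + 1, n_warmup, n_main, **nuts_kwargs)
    theta_samples = posterior.extract_theta(chain.samples)
    names = posterior.theta.free_names
    result = {
        "data": data,
        "posterior": posterior,
        "filter_chain": chain,
        "filter_theta": theta_samples,
        "theta_names": names,
        "filter_summaries": _theta_summaries(theta_samples, names),
        "manifest": {
            "experiment": "cancer_comparison", "scale": scale, "S": S,
            "N": data.n_individuals, "seed": seed, "sampler": "nuts",
            "n_warmup": n_warmup, "n_main": n_main,
            "filter": "gaussian", "theta_true": CANCER_THETA.tolist(),
            "evaluations": chain.n_evaluations,
        },
    }
    if compute_kl:
        result["filter_kl"] = diag.kl_population(
            model.population, CANCER_THETA, _full_thetas(posterior,
                                                         theta_samples))
    if run_traditional:
        nlme_model = get_model("cancer")
        hier = HierarchicalPosterior(data, nlme_model, prior)
        nchain = _run_nuts(hier, seed + 2, n_warmup, n_main, **nuts_kwargs)
        nt = hier.theta.n_free
        ntheta = np.stack([
            hier.theta.free_of(hier.theta.to_natural(row[:nt]))
            for row in nchain.samples])
        result["nlme_chain"] = nchain
        result["nlme_theta"] = ntheta
        result["nlme_summaries"] = _theta_summaries(ntheta, names)
        if compute_kl:
            result["nlme_kl"] = diag.kl_population(
                nlme_model.population, CANCER_THETA,
                _full_thetas_layout(hier.theta, ntheta))
    return result


def _full_thetas(posterior, theta_samples):
    return _full_thetas_layout(posterior.theta, theta_samples)


def _full_thetas_layout(layout, theta_samples):
    return np.stack([layout.full_theta(row) for row in theta_samples])


def run_egf(S=100, seed=1, n_warmup=None, n_main=None, full_budget=False,
            fix_koff=False, n_cells=1200, K=6, compute_kl=False,
            nuts_kwargs=None):
    """Joint EGF inference on pooled low/high EGF-concentration datasets.

    The noise scale is fixed to the data-generating value; the degradation
    rates are pooled and fixed.  With ``fix_koff`` the deactivation rate is
    also pinned, which resolves the kon-koff posterior correlation.
    """
    n_warmup, n_main = _budget(full_budget, n_warmup, n_main)
    data_low = generate_egf(c_l=2.0, n_cells=n_cells, K=K, seed=seed)
    data_high = generate_egf(c_l=10.0, n_cells=n_cells, K=K, seed=seed + 1)
    model_low = get_model("egf", c_l=2.0)
    model_high = get_model("egf", c_l=10.0)
    # conditions must share population/error objects
    model_high.population = model_low.population
    model_high.error = model_low.error
    fixed = {"mu_kdeg_r": EGF_THETA[5], "mu_kdeg_a": EGF_THETA[6],
             "mu_sigma": EGF_THETA[7]}
    if fix_koff:
        fixed["mu_koff"] = EGF_THETA[4]
    prior = default_egf_prior()
    posterior = FilterPosterior([data_low, data_high],
                                [model_low, model_high], prior, S=S,
                                filter_family="gaussian", fixed=fixed)
    chain = _run_nuts(posterior, seed + 2, n_warmup, n_main,
                      **(nuts_kwargs or {}))
    theta_samples = posterior.extract_theta(chain.samples)
    names = posterior.theta.free_names
    result = {
        "data_low": data_low, "data_high": data_high,
        "posterior": posterior, "chain": chain,
        "theta": theta_samples, "theta_names": names,
        "summaries": _theta_summaries(theta_samples, names),
        "manifest": {
            "experiment": "egf", "S": S, "seed": seed, "K": K,
            "n_cells": n_cells, "fix_koff": fix_koff, "fixed": fixed,
            "n_warmup": n_warmup, "n_main": n_main,
            "theta_true": EGF_THETA.tolist(),
            "evaluations": chain.n_evaluations,
        },
    }
    if not fix_koff:
        i, j = names.index("mu_kon"), names.index("mu_koff")
        result["kon_koff_correlation"] = float(np.corrcoef(
            theta_samples[:, i], theta_samples[:, j])[0, 1])
    return result


def run_filter_bias_study(filters=None, n_total=120, S=100, seed=1,
                          n_warmup=None, n_main=None, full_budget=False,
                          store_y_draws=False, nuts_kwargs=None):
    """Choice-of-filter bias on the two-variant (bimodal) cancer design.

    Runs filter inference once per requested filter and reports the KL
    divergence between the data-generating population distribution and each
    posterior-averaged inferred distribution.
    """
    n_warmup, n_main = _budget(full_budget, n_warmup, n_main)
    if filters is None:
        filters = [("gaussian", {}), ("gaussian_mixture", {"n_kernels": 2}),
                   ("gaussian_kde", {}), ("lognormal_kde", {})]
    data = generate_bimodal_cancer(n_total, seed=seed)
    prior = default_bimodal_prior()
    runs = {}
    for fam, opts in filters:
        model = get_model("cancer-bimodal")
        posterior = FilterPosterior(data, model, prior, S=S,
                                    filter_family=fam, filter_options=opts)
        chain = _run_nuts(posterior, seed + 3, n_warmup, n_main,
                          **(nuts_kwargs or {}))
        theta_samples = posterior.extract_theta(chain.samples)
        names = posterior.theta.free_names
        kl = diag.kl_population(model.population, BIMODAL_THETA,
                                _full_thetas(posterior, theta_samples))
        entry = {
            "posterior": posterior, "chain": chain, "theta": theta_samples,
            "theta_names": names,
            "summaries": _theta_summaries(theta_samples, names),
            "kl": kl,
        }
        if store_y_draws:
            entry["y_draws"] = posterior.extract_simulated_measurements(
                chain.samples)
        key = fam if not opts else f"{fam}(M={opts.get('n_kernels')})"
        runs[key] = entry
    return {
        "data": data, "runs": runs,
        "manifest": {
            "experiment": "filter_bias", "n_total": n_total, "S": S,
            "seed": seed, "n_warmup": n_warmup, "n_main": n_main,
            "filters": [k for k in runs], "theta_true": BIMODAL_THETA.tolist(),
        },
    }


def run_S_sweep(S_values=(3, 10, 100, 500), scale=27, seed=1, n_warmup=None,
                n_main=None, full_budget=False, nuts_kwargs=None):
    """Information loss vs number of simulated individuals (Gaussian filter).

    Uses the large (N = 90 * scale) cancer dataset and reports the KL to the
    data-generating population distribution per S.
    """
    n_warmup, n_main = _budget(full_budget, n_warmup, n_main)
    data = generate_cancer(scale, seed=seed)
    prior = default_cancer_prior()
    results = {}
    for S in S_values:
        model = get_model("cancer")
        posterior = FilterPosterior(data, model, prior, S=S,
                                    filter_family="gaussian")
        chain = _run_nuts(posterior, seed + 4, n_warmup, n_main,
                          **(nuts_kwargs or {}))
        theta_samples = posterior.extract_theta(chain.samples)
        results[S] = {
            "chain": chain, "theta": theta_samples,
            "theta_names": posterior.theta.free_names,
            "summaries": _theta_summaries(theta_samples,
                                          posterior.theta.free_names),
            "kl": diag.kl_population(model.population, CANCER_THETA,
                                     _full_thetas(posterior, theta_samples)),
        }
    return {
        "data": data, "runs": results,
        "manifest": {
            "experiment": "S_sweep", "S_values": list(S_values),
            "scale": scale, "N": data.n_individuals, "seed": seed,
            "n_warmup": n_warmup, "n_main": n_main,
        },
    }
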