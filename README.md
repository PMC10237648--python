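# snapinfer

Scalable Bayesian inference for nonlinear mixed-effects (NLME) models from
**snapshot time-series measurements** — datasets where every individual
(cell, patient) is measured exactly once, as produced by flow cytometry,
single-cell omics, or destructive assays.

## The problem and the method

An NLME model combines a deterministic time-series model `ȳ(ψ, t)` for one
individual, an error model `p(y | ψ, t)` for measurement noise, and a
population model `p(ψ | θ)` for the inter-individual variability (IIV) of the
individual-level parameters ψ.  The traditional hierarchical posterior

    log p(θ, Ψ | D) = Σ_ij log p(y_ij | ψ_i, t_j) + Σ_i log p(ψ_i | θ)
                    + log p(θ) + const

needs one model evaluation per measured individual, so its cost grows
linearly with N — intractable for snapshot datasets with thousands of cells.

**Filter inference** replaces the per-individual likelihood with an
approximate population-level likelihood built from `S` *simulated*
individuals: sample `ψ̃_s ~ p(ψ|θ)`, simulate measurements `ỹ_sj`, summarise
them at each time point with a parametric density — a *filter*
`p(y | Ỹ_j)` — and score the observed data against it:

    log p(D | θ) ≈ Σ_ij log p(y_ij | Ỹ_j(θ)).

The cost per likelihood evaluation is S model runs, independent of N.  Five
filters are provided: Gaussian (moment matching), lognormal, Gaussian
mixture with M kernels, and Gaussian/lognormal kernel density estimates with
the rule-of-thumb bandwidth `b² = (4/(3S))^{2/5} σ̃²`.

The estimator above is stochastic in θ.  Promoting the simulated
measurements and parameters to sampling dimensions gives the deterministic,
differentiable joint density

    log p(D, Ỹ, Ψ̃ | θ) = Σ_ij log p(y_ij | Ỹ_j) + Σ_sj log p(ỹ_sj | ψ_s, t_j)
                        + Σ_s log p(ψ_s | θ),

whose θ-marginal is the same posterior but which can be sampled with
gradient-based MCMC (NUTS).  All gradients in this package are analytic and
verified against finite differences.

## What is in the package

| module | contents |
| --- | --- |
| `snapinfer.dataset` | `SnapshotDataset` (long CSV ↔ N×K matrix views, NA handling) |
| `snapinfer.models` | time-series models (exponential tumour growth; EGF receptor ODE with exact matrix-exponential solutions and sensitivities), Gaussian/lognormal error models, population models (Normal, LogNormal, covariate-shifted Normal, point mass), registry `get_model("cancer" \| "egf" \| "cancer-bimodal")` |
| `snapinfer.filters` | the five filters with gradients w.r.t. the data point and every simulated measurement |
| `snapinfer.hierarchical` | traditional hierarchical NLME posterior with analytic gradients |
| `snapinfer.filter_inference` | stochastic estimator, `StochasticFilterTarget`, and the deterministic `FilterPosterior` (centered and non-centered parameterisations) |
| `snapinfer.samplers` | random-walk Metropolis–Hastings and an adaptive No-U-Turn sampler with evaluation counters |
| `snapinfer.synthetic` | seeded generators for the three study designs (cancer growth, EGF receptor, two-variant cancer) |
| `snapinfer.diagnostics` | ESS (Geyer), rank-normalised split R̂, KL divergence to the true population distribution, posterior predictive bands, accepted-summary-statistic traces |
| `snapinfer.experiments` | seeded end-to-end studies (`run_cancer_comparison`, `run_egf`, `run_filter_bias_study`, `run_S_sweep`) |

Short narrative scripts live in `examples/` (one per capability).

## Worked example

```python
from snapinfer.experiments import run_cancer_comparison

res = run_cancer_comparison(scale=1, S=100, seed=1, n_warmup=200, n_main=300)
for name in ("mu_y0", "mu_lambda"):
    f = res["filter_summaries"][name]["mean"]
    n = res["nlme_summaries"][name]["mean"]
    print(f"{name}: filter {f:.3f}  traditional NLME {n:.3f}")
print(f"KL to truth: filter {res['filter_kl']:.3f}, NLME {res['nlme_kl']:.3f}")
```

prints (N = 90 snapshot measurements, data generated with
θ = (μ_y0, σ_y0, μ_λ, σ_λ, μ_σ) = (10, 1, 2, 0.5, 0.8)):

```
mu_y0: filter 10.031  traditional NLME 10.025
mu_lambda: filter 1.889  traditional NLME 1.904
KL to truth: filter 0.104, NLME 0.108
```

Filter inference and the exact hierarchical baseline give nearly identical
posteriors: both recover the population means, both leave the noise scale
μ_σ prior-dominated (snapshot data cannot attribute the spread at t=0 to
noise versus initial-volume IIV), and both carry the same residual KL to the
data-generating population distribution, which is dominated by having only
90 individuals.  Rerunning with `scale=27` (N = 2430, where the traditional
likelihood would cost 27× more per evaluation while the filter posterior
costs exactly the same) drops the KL to about 0.011.

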