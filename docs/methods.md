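# Methods

This note records the modelling assumptions, numerical choices, and default
parameters behind `snapinfer`, and what the synthetic studies do and do not
demonstrate.

## Model structure

An NLME model is a triple (time-series model, error model, population
model).  The individual-level parameter vector ψ consists of the mechanistic
parameters followed by the noise scale σ.  Population models are products of
independent per-dimension components:

* `Normal(μ_k, σ_k)` — the default for mechanistic parameters;
* `LogNormal(location, scale)` — for strictly positive parameters;
* `CovariateNormal(μ_base, Δμ, σ)` — mean shifted by `χ·Δμ` for a binary
  covariate χ (e.g. a moderate vs aggressive disease variant);
* `PointMass(value)` — a parameter pooled across individuals.  It is never a
  free individual-level sampling dimension and contributes nothing to the
  population log-density; gradients with respect to its θ value flow through
  every place the pooled value is used (e.g. the noise scale in the error
  terms).

Error models are Gaussian (`y = ȳ + ε`) or lognormal with the model output
as the median (`ln y ~ N(ln ȳ, σ²)`); the lognormal parameterisation makes σ
unit-free.

### Concrete models

* **Early cancer growth** — `ȳ(ψ, t) = y0·e^{λt}` with Gaussian noise;
  θ = (μ_y0, σ_y0, μ_λ, σ_λ, μ_σ), the noise scale pooled as a point mass.
* **EGF receptor** — linear two-state ODE for inactive/active receptor
  concentrations under constant ligand concentration c_l, zero initial
  conditions, lognormal noise.  (p, kon) vary across cells with Normal
  components (the family is a package choice; exposed via the population
  model); (koff, kdeg_r, kdeg_a, σ) are pooled point masses.  Because the
  system is linear time-invariant, trajectories *and* forward sensitivities
  are computed exactly via the matrix exponential of an augmented
  (states + sensitivities + constant input) system, batched across cells;
  tests cross-check against an LSODA integration at rtol 1e-10.
* **Two-variant cancer growth** — the cancer model with a covariate-shifted
  growth-rate mean μ_λ(χ) = μ_λ,base + χ·Δμ_λ, giving a bimodal population
  distribution.

## Filters

All five filters use the empirical variance with the S−1 denominator,
including inside the KDE bandwidth rule `b² = (4/(3S))^{2/5} σ̃²` (the exact
value of the constant at S=100 and unit variance is 0.177818).  The mixture
filter assigns contiguous blocks of S/M simulated individuals to kernels in
storage order; simulated covariates are grouped (all χ=0 first), so with
M=2 the kernels align with the subpopulations.  M=S is rejected — block
variances would be undefined — and users wanting one kernel per simulation
use the KDE filters, which carry a bandwidth instead.  By default the
bandwidth is treated as a function of the simulated measurements inside the
deterministic posterior, so its gradient terms are included; a
`freeze_bandwidth` flag drops them.

Filter construction fails (and the deterministic posterior returns −∞, not
an exception) when a lognormal-family filter meets non-positive simulated
measurements or a mixture block has zero variance.

## Deterministic filter posterior and parameterisation

The state is (θ free dims, Ψ̃ = S×(free ψ dims), Ỹ = S×K×observables); for
the cancer design with S=100, K=6 and 5 free θ dimensions this is
5 + 200 + 600 = 805 dimensions.  Positive parameters are sampled on the log
scale with Jacobian corrections; model code always sees natural scale.

Two exact parameterisations are provided:

* **centered** — the state holds natural-scale Ψ̃ and Ỹ (log-scale Ỹ under
  a lognormal error model), and the log-density is the sum of the three
  terms above;
* **non-centered** (default for sampling) — the state holds standard-normal
  innovations: ψ_s = μ(θ, χ_s) + σ(θ)·η_s and ỹ_sj = ȳ_sj + σ_s·ε_sj
  (multiplicatively under lognormal noise).  The population and
  simulated-measurement terms reduce to standard normal densities and only
  the data term couples the state.  This removes the hierarchical funnel
  between θ-level scales and individual-level values: on the N=90 cancer
  problem NUTS needs ≈20k gradient evaluations for 500 iterations instead
  of ≈215k.  The θ-marginal is identical; tests verify both gradients
  against finite differences and the term decomposition on the natural
  scale.

Evaluation cost contracts are enforced with counters: one trajectory per
simulated individual per evaluation (exactly S, independent of N, with the
single trajectory covering all measurement times reused by the data and
error terms), and one per measured individual (N) for the hierarchical
baseline.

## Samplers

Random-walk MH uses component-wise Gaussian proposals; optional warmup
adaptation tunes a global scale factor to 23.4% acceptance
(Robbins–Monro) and, in `diag` mode, per-dimension scales from the running
chain standard deviations.

NUTS is a from-scratch implementation of tree doubling with slice sampling,
dual-averaging step-size adaptation (target acceptance 0.8), and a diagonal
mass matrix estimated from the middle 70% of warmup (regularised toward
unity, Stan-style), after which dual averaging restarts.  Divergences
(energy error > 1000) are counted and reported, never fatal; maximum tree
depth is 10.  Each evaluation includes the gradient, so the log-posterior
and gradient counters coincide.

## Synthetic-data generators

The generators are the study designs, not tunable fixtures:

* **cancer** — 15·m individuals per time point at 6 evenly spaced times on
  [0, 0.6] *including 0* (the t=0 design is what makes the noise/IIV
  confounding visible: measurement variance there is σ_y0² + μ_σ² = 1.64);
  θ_true = (10, 1, 2, 0.5, 0.8); m ∈ {1,3,9,27} gives N = 90…2430.
* **EGF** — 1200 cells per condition over 25 min, both observables per cell,
  lognormal noise with scale 0.05, population parameters
  (1.7, 0.05, 1.7, 0.05, 8, 0.25, 0.015, 0.05).  The number of time points
  is not part of the design as stated, so the default is K=6 with
  1200/K cells each; the grid is 25·(1..6)/6 — t=0 is excluded because the
  zero initial concentrations make lognormal noise undefined there.
* **bimodal cancer** — (10, 1, 2, 2, 0.5, 0.8) with half the individuals per
  variant, balanced within every time point so time is not confounded with
  variant.

Each individual appears at exactly one time point, assigned deterministically
in blocks; IDs are zero-padded so lexicographic and numeric orders agree.
All generators are reproducible under a seed and round-trip exactly through
the CSV reader/writer (`%.17g` formatting, round-trip float parsing).

What the generators do *not* emulate: real measurement-process artefacts
(detection limits, gating, batch effects), model misspecification (the
fitted time-series model is the generating one), and non-snapshot designs.
Passing tests therefore demonstrate correctness and the method's statistical
behaviour under its own assumptions, not robustness to misspecified real
data.

## Priors

The study priors are package defaults, chosen to cover the data-generating
values without centring every parameter on the truth:

| parameter | prior | note |
| --- | --- | --- |
| μ_y0 | Normal(9, 3) | |
| σ_y0 | LogNormal(ln 1, 0.5) | |
| μ_λ, μ_λ,base | Normal(1.5, 1.5) | |
| σ_λ | LogNormal(ln 0.5, 0.5) | |
| μ_σ | LogNormal(ln 0.75, 0.2) | concentrates on 0.5–1: an informative noise prior is what makes snapshot inference with small S workable |
| Δμ_λ | LogNormal(0, 0.75) | positive support pins the subpopulation labels; deliberately *not* centred on the true shift 2, so the filter choice — not the prior — must resolve the split |
| μ_p, μ_kon | Normal(1.5, 0.5) | |
| σ_p, σ_kon | LogNormal(ln 0.05, 0.5) | |
| μ_koff | LogNormal(ln 6, 0.5) | |

In the EGF studies the noise scale and the two degradation rates are fixed
to their data-generating values; the deactivation rate koff is either free
(exposing its strong posterior correlation with μ_kon) or fixed.

## Diagnostics

ESS uses Geyer's initial-monotone-sequence estimator on FFT
autocovariances (cross-checked against arviz); R̂ is arviz's rank-normalised
split-R̂.  The KL divergence between the true population distribution and
the posterior-averaged inferred distribution E_{θ|D}[p(ψ|θ)] is computed by
tensor-grid quadrature over the free ψ dimensions (default 120 points per
dimension, grid spanning ±6 true standard deviations; a warning reports any
mass coverage below 99.9%), with the posterior average taken pointwise over
(thinned, ≤200) draws; covariate populations are marginalised with equal
weights.  The quadrature agrees with the closed-form Gaussian KL to 1e-4.

## Problem sizes and budgets

Experiments default to 200 warmup + 300 main NUTS iterations and one chain
— enough for the parameter-recovery and filter-comparison conclusions at
the study sizes used here; `full_budget=True` switches to 500+1000.  The
stochastic/deterministic agreement check runs MH with 20k/60k iterations on
the N=30, S=20 problem.  The test suite and the acceptance script use these
scaled budgets throughout; the EGF smoke runs additionally cap the NUTS
tree depth at 7 because short warmup on that stiffer posterior otherwise
spends long excursions at maximal depth.

## Known limitations

* The EM-fitted Gaussian mixture filter and adaptive/plug-in bandwidth
  selection are out of scope; the mixture filter uses fixed block
  assignment.
* The stochastic filter target is sampled as a noisy MH target; its
  agreement with the deterministic posterior is exact only in
  distributional terms verified empirically (the log-likelihood estimator
  is not unbiased on the likelihood scale).
* Single-machine, single-chain oriented: multi-chain runs are loops over
  seeds; R̂ is provided but chains are not parallelised.
* The EGF study at full size (S=100, 2×1200 cells) is supported but takes
  tens of minutes on one CPU because each gradient evaluation solves 2·S
  augmented matrix exponentials.
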