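"""The five population filters and their approximation behaviour.

A filter turns S simulated measurements at one time point into an
approximate measurement density.  This script builds each filter from the
same simulations and evaluates it against the exact population measurement
distribution of the cancer model at t = 0 (a Normal(10, 1.64), since initial
volumes are N(10,1) and noise is N(0, 0.8^2)).
"""

import numpy as np
from scipy.stats import norm

from snapinfer import build_filter, get_model, kde_bandwidth

rng = np.random.default_rng(2)
model = get_model("cancer")
theta = np.array([10.0, 1.0, 2.0, 0.5, 0.8])

S = 100
psi = model.population.sample(theta, S, rng)
sims = psi[:, 0] + 0.8 * rng.standard_normal(S)   # measurements at t = 0

grid = np.linspace(5, 15, 201)
exact = norm.logpdf(grid, 10.0, np.sqrt(1.0 + 0.8**2))

print(f"S = {S} simulated measurements at t = 0; "
      f"KDE bandwidth^2 = {kde_bandwidth(sims):.4f}")
print(f"{'filter':>22}  mean abs log-density error vs exact")
for family, opts in [("gaussian", {}), ("lognormal", {}),
                     ("gaussian_mixture", {"n_kernels": 2}),
                     ("gaussian_kde", {}), ("lognormal_kde", {})]:
    filt = build_filter(family, sims, **opts)
    err = np.mean(np.abs(filt.logpdf(grid) - exact))
    label = family if not opts else f"{family}(M=2)"
    print(f"{label:>22}  {err:.3f}")
print("All filters approximate the true N(10, 1.64) closely here because the"
      " underlying distribution is unimodal; their differences matter for"
      " multi-modal populations (see example 05).")
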