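"""Filter inference vs traditional NLME on the cancer growth study (N=90).

Runs NUTS on the deterministic filter posterior (Gaussian filter, S=100) and
on the exact hierarchical NLME posterior, then compares posterior summaries,
the KL divergence of the inferred population distribution to the truth, and
the evaluation-cost contracts.  Takes a couple of minutes.
"""

from snapinfer.experiments import run_cancer_comparison

res = run_cancer_comparison(scale=1, S=100, seed=1, n_warmup=200, n_main=300)

print(f"{'parameter':>14} {'truth':>6} {'filter mean (90% CI)':>28} "
      f"{'NLME mean (90% CI)':>28}")
truth = dict(zip(res["theta_names"], [10.0, 1.0, 2.0, 0.5, 0.8]))
for name in res["theta_names"]:
    f = res["filter_summaries"][name]
    n = res["nlme_summaries"][name]
    print(f"{name:>14} {truth[name]:>6} "
          f"{f['mean']:>9.3f} [{f['ci90'][0]:.3f}, {f['ci90'][1]:.3f}]   "
          f"{n['mean']:>9.3f} [{n['ci90'][0]:.3f}, {n['ci90'][1]:.3f}]")

print(f"\nKL(truth || inferred population): filter {res['filter_kl']:.3f}, "
      f"NLME {res['nlme_kl']:.3f}")
print("Both posteriors centre on the data-generating means; the noise scale "
      "mu_sigma stays prior-dominated because snapshot data cannot separate "
      "noise from initial-volume variability.")
print(f"NUTS evaluations: filter {res['filter_chain'].n_evaluations}, "
      f"NLME {res['nlme_chain'].n_evaluations} (each evaluation of the "
      "filter posterior costs S=100 model runs; the NLME posterior costs "
      "N=90 and grows linearly with N).")
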