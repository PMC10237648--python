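"""Information loss from the filter choice on a bimodal population.

Two cancer variants shift the mean growth rate by delta = 2, giving a
bimodal growth-rate distribution.  A single Gaussian filter only matches
means and variances per time point and cannot localise the two modes from
120 patients; a two-kernel mixture filter (kernels aligned with the
subpopulations) resolves them; KDE filters resolve the modes but
underestimate the inter-individual variability.  ~2-3 minutes.
"""

from snapinfer.experiments import run_filter_bias_study

res = run_filter_bias_study(n_total=120, S=100, seed=2, n_warmup=200,
                            n_main=300)

print(f"{'filter':>22} {'KL to truth':>12} {'sigma_lambda (true 0.5)':>24} "
      f"{'delta (true 2)':>15}")
for name, run in res["runs"].items():
    s = run["summaries"]
    print(f"{name:>22} {run['kl']:>12.3f} "
          f"{s['sigma_lambda']['mean']:>24.3f} "
          f"{s['delta_mu_lambda']['mean']:>15.3f}")
print("The mixture filter attains the smallest KL and recovers the variant "
      "shift; the Gaussian filter blurs the split into a wider sigma_lambda; "
      "KDE filters shrink sigma_lambda well below the true 0.5.")
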