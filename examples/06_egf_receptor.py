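"""EGF receptor activation: filter inference on a two-observable ODE model.

Cells exposed to a constant EGF concentration produce inactive receptors
(c_r) that activate on ligand binding; both concentrations are snapshot-
measured with lognormal noise across two EGF conditions (2 and 10 ng/mL).
This is a strongly scaled-down run (60 cells per condition, S=12); pass
full_budget=True and n_cells=1200 for the full design.  ~5 minutes.
"""

from snapinfer.experiments import run_egf
from snapinfer.models import EGFRModel

model = EGFRModel(c_l=2.0)
print("steady state at the data-generating rates (c_l = 2 ng/mL):",
      model.steady_state([1.7, 1.7, 8.0, 0.25, 0.015]).round(3),
      "(inactive, active receptor in ng/mL)")

res = run_egf(S=12, seed=3, n_warmup=40, n_main=60, fix_koff=True,
              n_cells=60, K=6, nuts_kwargs={"max_depth": 7})
print(f"\nkoff fixed to 8/min; inferred population parameters "
      f"(truth: mu_p=1.7, mu_kon=1.7):")
for name, summ in res["summaries"].items():
    print(f"  {name:>10}: {summ['mean']:.3f} "
          f"[{summ['ci90'][0]:.3f}, {summ['ci90'][1]:.3f}]")

res_free = run_egf(S=12, seed=3, n_warmup=40, n_main=60, fix_koff=False,
                   n_cells=60, K=6, nuts_kwargs={"max_depth": 7})
print(f"\nwith koff free, corr(mu_kon, mu_koff) = "
      f"{res_free['kon_koff_correlation']:.2f} — activation and deactivation "
      "rates are not separately identifiable from these snapshots, which is "
      "why fixing koff sharpens the kon estimate.")
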