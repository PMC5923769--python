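"""Propagate spill-volume and concentration uncertainty through the model.

Runs the seeded 1000-trial Monte Carlo for the drinking-water scenario,
prints the six-number summaries of the three partitioned totals, and the
rank-correlation sensitivity of each total to the spill volume.
"""

import frackrisk as fr

registry = fr.load_default_registry()
result = fr.run_monte_carlo(
    registry,
    fr.drinking_water_scenario(),
    fr.drinking_water_factors(),
    n_trials=1000,
    seed=17,
)

summary = fr.summarize(result)
print("totals over 1000 trials (median / 95th percentile):")
for name, row in summary.totals_table.iterrows():
    print(f"  {name:26s} {row['median']:.3e} / {row['p95']:.3e}")

sens = fr.spearman_sensitivity(result)
spill = sens[sens["input"] == "spill_volume"]
print("\nSpearman rho of spill volume against each total:")
for r in spill.itertuples():
    print(f"  {r.output:26s} rho = {r.rho:.3f} {r.significance}")

print("\nA rho near 1 means the spilled volume, not any single analyte's"
      " concentration, drives the simulated risk.")
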