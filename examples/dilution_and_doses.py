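"""Deterministic walkthrough: one spill, one analyte, all three pathways.

A median-sized spill (128 L) of flowback water carrying benzene at its
95th-percentile concentration (0.17 mg/L) mixes into a 44-million-litre
drinking-water reservoir.  We compute the diluted concentration, the
chronic daily intakes for ingestion, inhalation and dermal contact, and the
resulting excess lifetime cancer risk per pathway.
"""

import frackrisk as fr

registry = fr.load_default_registry()
factors = fr.drinking_water_factors()
scenario = fr.drinking_water_scenario()
benzene = registry["Benzene"]

c_w = fr.dilute(0.17, 128.0, scenario.pond_volume)
print(f"diluted benzene concentration: {c_w:.3e} mg/L")
print(f"air concentration (VF = {factors.volatilization_factor} L/m3): "
      f"{fr.air_concentration(c_w, factors):.3e} mg/m3")

for r in fr.assess_contaminant(benzene, c_w, factors, scenario):
    print(f"  {r.pathway:10s} dose {r.dose:.3e} mg/kg-day -> risk {r.cancer_risk:.3e}")

total = sum(r.cancer_risk for r in fr.assess_contaminant(benzene, c_w, factors, scenario))
print(f"total benzene cancer risk: {total:.3e}  (target 1e-6)")
print("Risks here are per-lifetime excess cancer probabilities; a value of"
      " 1e-6 means one extra cancer per million people so exposed.")
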