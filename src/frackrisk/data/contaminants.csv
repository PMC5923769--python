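name,analyte_class,oral_slope_factor,inhalation_unit_risk,oral_reference_dose,gi_absorption_fraction,dermal_permeability,henry_constant,molecular_weight,rad_ingestion_sf,rad_inhalation_sf,rad_immersion_sf,dist_family,dist_median,dist_p95,n_samples,concentration_units,notes
Arsenic,carcinogen,1.5,4.3e-3,,1.0,1e-3,,74.92,,,,logistic,0.05,0.09,219,mg/L,SF/IUR IRIS
Benzene,carcinogen,0.055,7.8e-6,,1.0,1.5e-2,5.5e-3,78.11,,,,lognormal,0.01,0.17,123,mg/L,SF/IUR IRIS; Kp RAGS Part E
Benzo(a)pyrene,carcinogen,7.3,1.1e-3,,1.0,0.7,4.6e-7,252.3,,,,logistic,0.01,0.015,111,mg/L,SF/IUR IRIS (pre-2017); printed anchors equal at 2 dp; p95 = median + half printing resolution
Dibromochloromethane,carcinogen,0.084,,,1.0,3.9e-3,7.8e-4,208.28,,,,lognormal,0.01,0.02,120,mg/L,SF IRIS; distribution is a documented placeholder (trace THM; analyte absent from the study's distribution table)
"1,2-Dichloroethane",carcinogen,0.091,2.6e-5,,1.0,4.2e-3,9.8e-4,98.96,,,,lognormal,0.01,0.02,143,mg/L,SF/IUR IRIS
Heptachlor,carcinogen,4.5,1.3e-3,,1.0,5.0e-2,2.9e-4,373.32,,,,pareto,0.01,0.02,73,mg/L,SF/IUR IRIS; Kp from Potts-Guy correlation
Heptachlor epoxide,carcinogen,9.1,2.6e-3,,1.0,2.0e-2,9.5e-6,389.32,,,,lognormal,0.01,0.02,73,mg/L,SF/IUR IRIS; Kp from Potts-Guy correlation
Lead,carcinogen,8.5e-3,1.2e-5,,1.0,1e-4,,207.2,,,,lognormal,0.03,0.20,212,mg/L,SF CalEPA
Pentachlorophenol,carcinogen,0.4,5.1e-6,,1.0,0.12,2.4e-8,266.34,,,,weibull,0.01,0.02,111,mg/L,SF IRIS 2010
Vinyl chloride,carcinogen,0.72,4.4e-6,,1.0,5.6e-3,2.78e-2,62.5,,,,lognormal,0.01,0.17,120,mg/L,SF/IUR IRIS (adult); distribution is a documented benzene-analog placeholder (analyte absent from the study's distribution table; <5% detects)
Aluminum,noncarcinogen,,,1.0,1.0,1e-3,,26.98,,,,lognormal,0.29,2.80,220,mg/L,RfD PPRTV
Antimony,noncarcinogen,,,4e-4,1.0,1e-3,,121.76,,,,triangular,0.05,0.09,186,mg/L,RfD IRIS
Barium,noncarcinogen,,,0.2,0.07,1e-3,,137.33,,,,lognormal,164.00,20009.00,220,mg/L,RfD IRIS; GI absorption RAGS Part E
Beryllium,noncarcinogen,,,2e-3,0.007,1e-3,,9.01,,,,minimum_extreme,0.01,0.02,216,mg/L,RfD IRIS; printed anchors out of order (0.02/0.01); swapped
Cadmium,noncarcinogen,,,5e-4,0.025,1e-3,,112.41,,,,lognormal,0.01,0.06,218,mg/L,RfD IRIS (water)
Copper,noncarcinogen,,,0.04,1.0,1e-3,,63.55,,,,lognormal,0.335,0.45,219,mg/L,RfD HEAST; printed median 33500.00 inconsistent with p95; read as 0.335 (misplaced decimal)
Iron,noncarcinogen,,,0.7,1.0,1e-3,,55.85,,,,lognormal,29.70,178.20,233,mg/L,RfD PPRTV
Manganese,noncarcinogen,,,0.024,0.04,1e-3,,54.94,,,,lognormal,2.17,12.40,220,mg/L,RfD IRIS with drinking-water modifying factor; GI absorption RAGS Part E
Nitrite as N,noncarcinogen,,,0.1,1.0,1e-3,,46.01,,,,lognormal,0.11,60.81,91,mg/L,RfD IRIS; printed p95 '060.81' read as 60.81
Thallium,noncarcinogen,,,1e-5,1.0,1e-3,,204.38,,,,weibull,0.02,0.28,192,mg/L,RfD PPRTV (soluble salts)
Radium-226,radionuclide,,,,,,,,3.85e-10,2.74e-9,6.1e-10,lognormal,1300.00,48190.20,34,pCi/L,Slope factors HEAST radionuclide tables (+D); immersion coefficient FGR-12-order estimate; printed median 1.30 inconsistent with the study's sensitivity ordering; read as 1300 (x1000 slip)
Radium-228,radionuclide,,,,,,,,1.04e-9,5.18e-9,1.1e-9,lognormal,230.00,4470.00,30,pCi/L,Slope factors HEAST radionuclide tables (+D); immersion coefficient FGR-12-order estimate; printed median 0.23 read as 230 (x1000 slip)
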