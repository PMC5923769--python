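name,mcl,units,notes
Arsenic,0.010,mg/L,MCL
Benzene,0.005,mg/L,MCL
Benzo(a)pyrene,0.0002,mg/L,MCL
Dibromochloromethane,0.08,mg/L,total-THM MCL
"1,2-Dichloroethane",0.005,mg/L,MCL
Heptachlor,0.0004,mg/L,MCL
Heptachlor epoxide,0.0002,mg/L,MCL
Lead,0.015,mg/L,action level
Pentachlorophenol,0.001,mg/L,MCL
Vinyl chloride,0.002,mg/L,MCL
Aluminum,0.2,mg/L,secondary standard
Antimony,0.006,mg/L,MCL
Barium,2.0,mg/L,MCL
Beryllium,0.004,mg/L,MCL
Cadmium,0.005,mg/L,MCL
Copper,1.3,mg/L,action level
Iron,0.3,mg/L,secondary standard
Manganese,0.05,mg/L,secondary standard
Nitrite as N,1.0,mg/L,MCL
Thallium,0.002,mg/L,MCL
Radium-226,5.0,pCi/L,combined radium MCL
Radium-228,5.0,pCi/L,combined radium MCL
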