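analyte_id,rfd_mg_kg_day,csf_per_mg_kg_day,mrl_low,mrl_high,mrl_units,provenance
aldrin,0.0003,217,,10,ug_per_kg_wet,published survey report (ambiguous row; OSF 217 adopted)
ddd,,0.24,,1250,ug_per_kg_wet,published survey report
dde,,,,1250,ug_per_kg_wet,published survey report
ddt,,,,1250,ug_per_kg_wet,published survey report
dieldrin,,0.34,10,100,ug_per_kg_wet,published survey report (printed OSF 0.34; EPA IRIS lists 16)
endosulfan_i,0.006,,,50,ug_per_kg_wet,published survey report
endosulfan_ii,,,,50,ug_per_kg_wet,published survey report
endosulfan_sulfate,,,,50,ug_per_kg_wet,published survey report
endrin,,,10,50,ug_per_kg_wet,published survey report
endrin_aldehyde,,,,10,ug_per_kg_wet,published survey report
endrin_ketone,0.0003,,,50,ug_per_kg_wet,published survey report
heptachlor,0.00005,4.50,10,20,ug_per_kg_wet,published survey report
heptachlor_epoxide,0.00001,9.10,,10,ug_per_kg_wet,published survey report
methoxychlor,0.005,,,10,ug_per_kg_wet,published survey report
alpha_hch,0.008,6.3,10,250,ug_per_kg_wet,published survey report
beta_hch,,1.8,10,250,ug_per_kg_wet,published survey report
gamma_hch,0.0003,,,250,ug_per_kg_wet,published survey report
delta_hch,,0.24,,250,ug_per_kg_wet,published survey report
alpha_chlordane,,,2,50,ug_per_kg_wet,published survey report
gamma_chlordane,,,,,,no MRL established
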