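analyte_id,class,family,mean,sd,detection_frequency_pct,n,units,basis,season,nd
aldrin,ocp,drin,0.00062,,3.49,86,mg_per_kg,wet,,false
ddd,ocp,DDx,0.0003,,10.47,86,mg_per_kg,wet,,false
dde,ocp,DDx,0.00012,,26.74,86,mg_per_kg,wet,,false
dieldrin,ocp,drin,0.00014,,15.12,86,mg_per_kg,wet,,false
endosulfan_i,ocp,endosulfan,0.00022,,32.56,86,mg_per_kg,wet,,false
endosulfan_ii,ocp,endosulfan,0.0002,,22.09,86,mg_per_kg,wet,,false
endosulfan_sulfate,ocp,endosulfan,0.0027,,11.63,86,mg_per_kg,wet,,false
endrin,ocp,drin,0.002,,16.28,86,mg_per_kg,wet,,false
endrin_aldehyde,ocp,drin,0.00005,,33.72,86,mg_per_kg,wet,,false
endrin_ketone,ocp,drin,0.0025,,13.95,86,mg_per_kg,wet,,false
heptachlor,ocp,chlordane,0.00011,,1.16,86,mg_per_kg,wet,,false
heptachlor_epoxide,ocp,chlordane,0.0011,,3.49,86,mg_per_kg,wet,,false
methoxychlor,ocp,none,0.0052,,18.6,86,mg_per_kg,wet,,false
alpha_chlordane,ocp,chlordane,0.00009,,3.49,86,mg_per_kg,wet,,false
gamma_chlordane,ocp,chlordane,0.022,,60.47,86,mg_per_kg,wet,,false
alpha_hch,ocp,HCH,0.025,,12.79,86,mg_per_kg,wet,,false
beta_hch,ocp,HCH,0.0035,,6.98,86,mg_per_kg,wet,,false
delta_hch,ocp,HCH,0.005,,10.47,86,mg_per_kg,wet,,false
gamma_hch,ocp,HCH,0.0017,,1.16,86,mg_per_kg,wet,,false
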