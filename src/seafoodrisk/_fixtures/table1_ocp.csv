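analyte_id,class,family,mean,sd,detection_frequency_pct,n,units,basis,season,nd
aldrin,ocp,drin,0.80,0.93,3.49,86,ug_per_kg,wet,,false
ddd,ocp,DDx,0.11,0.07,10.47,86,ug_per_kg,wet,,false
dde,ocp,DDx,0.12,0.19,26.74,86,ug_per_kg,wet,,false
ddt,ocp,DDx,ND,ND,2.33,86,ug_per_kg,wet,,true
dieldrin,ocp,drin,0.13,0.23,15.12,86,ug_per_kg,wet,,false
endosulfan_i,ocp,endosulfan,0.25,0.38,32.56,86,ug_per_kg,wet,,false
endosulfan_ii,ocp,endosulfan,0.21,0.16,22.09,86,ug_per_kg,wet,,false
endosulfan_sulfate,ocp,endosulfan,4.93,9.85,11.63,86,ug_per_kg,wet,,false
endrin,ocp,drin,2.22,4.94,16.28,86,ug_per_kg,wet,,false
endrin_aldehyde,ocp,drin,0.05,0.09,33.72,86,ug_per_kg,wet,,false
endrin_ketone,ocp,drin,4.93,6.96,13.95,86,ug_per_kg,wet,,false
heptachlor,ocp,chlordane,0.17,0,1.16,86,ug_per_kg,wet,,false
heptachlor_epoxide,ocp,chlordane,0.07,2.02e-6,3.49,86,ug_per_kg,wet,,false
methoxychlor,ocp,none,6.14,22.8,18.6,86,ug_per_kg,wet,,false
alpha_hch,ocp,HCH,24.7,32.3,12.79,86,ug_per_kg,wet,,false
beta_hch,ocp,HCH,3.52,7.14,6.98,86,ug_per_kg,wet,,false
gamma_hch,ocp,HCH,1.7,15,1.16,86,ug_per_kg,wet,,false
delta_hch,ocp,HCH,5.33,13.2,10.47,86,ug_per_kg,wet,,false
alpha_chlordane,ocp,chlordane,0.02,,3.49,86,ug_per_kg,wet,,false
gamma_chlordane,ocp,chlordane,22.94,72.5,60.47,86,ug_per_kg,wet,,false
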