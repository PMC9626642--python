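analyte_id,class,family,mean,sd,detection_frequency_pct,n,units,basis,season,nd
cd,trace_metal,none,1.45,,1.16,86,mg_per_kg,dry,,false
cu,trace_metal,none,5.06,21.06,41.86,86,mg_per_kg,dry,,false
fe,trace_metal,none,80.52,73.54,100,86,mg_per_kg,dry,,false
mn,trace_metal,none,6.13,3.86,38.37,86,mg_per_kg,dry,,false
ni,trace_metal,none,8.06,3.53,32.56,86,mg_per_kg,dry,,false
pb,trace_metal,none,18.42,16.53,83.72,86,mg_per_kg,dry,,false
zn,trace_metal,none,189.55,1062.73,100,86,mg_per_kg,dry,,false
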