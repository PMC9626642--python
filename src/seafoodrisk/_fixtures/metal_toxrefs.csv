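analyte_id,rfd_mg_kg_day,csf_per_mg_kg_day,mrl_low,mrl_high,mrl_units,provenance
cd,0.001,6.3,0.00003,0.002,mg_per_kg_dry,RfD US EPA IRIS; slope inhalation-derived value commonly applied in dietary ILCR studies; MRL range from survey report
cu,0.04,,0.03,0.12,mg_per_kg_dry,RfD US EPA HEAST; MRL range from survey report
fe,0.7,,0.7,0.8,mg_per_kg_dry,RfD US EPA provisional; MRL range from survey report
mn,0.14,,1,1,mg_per_kg_dry,RfD US EPA IRIS (dietary); MRL from survey report
ni,0.02,1.7,0.0005,0.14,mg_per_kg_dry,RfD US EPA IRIS (soluble salts); slope OEHHA inhalation-derived; MRL range from survey report
pb,0.0035,0.0085,0.0003,0.004,mg_per_kg_dry,RfD JECFA PTWI-derived; slope OEHHA oral; MRL range from survey report
zn,0.3,,0.03,0.12,mg_per_kg_dry,RfD US EPA IRIS; MRL range from survey report
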