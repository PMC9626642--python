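# Default exposure scenario: Mexican adult fish-consumption point estimate.
vir_d_g_per_day: 32.88
bw_kg: 74.3
ed_years: 26
ef_days_per_year: 365
at_days: 9490
mode: paper_compat
arl: 1.0e-5
nd_policy: zero
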