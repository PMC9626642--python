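"""What happens if consumption rises from one small meal to three per day?

Sweeps the consumption rate from the national average (32.88 g/day) to
120 g/day (about three tacos) and prints how the lead THQ and the OCP
cancer-risk picture respond. All indices are linear in the rate.
"""

from seafoodrisk import (
    DEFAULT_ANALYTES,
    ExposureScenario,
    RiskConfig,
    ToxicityReference,
    build_registry,
    convert_units,
    fixture_bundle,
    read_concentration_table,
    read_toxicity_table,
    safe_consumption_rate,
    scenario_sweep,
    thq_tm,
)

fb = fixture_bundle()
metals = read_concentration_table(fb["table1_tm.csv"])
refs = read_toxicity_table(fb["metal_toxrefs.csv"])
registry = build_registry(DEFAULT_ANALYTES, refs)
scenario, config = ExposureScenario(), RiskConfig()

table = scenario_sweep(metals, registry, scenario, config, [32.88, 65.76, 120.0])
pb = table[table["analyte_id"] == "pb"]
print("lead (Pb) THQ vs consumption rate:")
for _, row in pb.iterrows():
    marker = "  << above 1: non-cancer risk" if row["thq"] > 1 else ""
    print(f"  {row['rate_g_per_day']:7.2f} g/day -> THQ {row['thq']:.3f}{marker}")

pb_ref = registry.reference("pb")
pb_conc = next(r.mean_concentration for r in metals if r.analyte_id == "pb")
vir_star = safe_consumption_rate(pb_conc, pb_ref, scenario, "thq", config)
print(f"\nintake at which Pb THQ = 1: {vir_star:.2f} g/day")
check = thq_tm(pb_conc, pb_ref.rfd, ExposureScenario(vir_d=vir_star))
print(f"forward check: THQ({vir_star:.2f} g/day) = {check:.12f}")
print("\nTHQ scales exactly with the rate, so every block is the base block")
print(f"times rate/32.88 (120/32.88 = {120/32.88:.4f}).")
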