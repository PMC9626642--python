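"""Simulate a monitoring survey and push it through the whole pipeline.

Builds a hurdle-lognormal generator from the bundled OCP summary table
(detection probability = reported frequency; lognormal moments matched to
the reported mean +/- SD), draws an 86-specimen survey across five
seasons, re-summarises it, and compares recovered summaries with the
generating ones.
"""

from seafoodrisk import (
    fixture_bundle,
    generate_survey,
    read_concentration_table,
    records_from_summary,
    summarize_survey,
    survey_config_from_summary,
)

template = read_concentration_table(fixture_bundle()["table1_ocp.csv"])
config = survey_config_from_summary(template, seed=2024)
table = generate_survey(config)
print(f"survey: {config.n_specimens} specimens x {len(config.analytes)} analytes, "
      f"{table['nd'].mean():.0%} of measurements below LOD\n")

summary = summarize_survey(table).set_index("analyte_id")
print(f"{'analyte':22s} {'freq in':>8s} {'freq out':>9s} {'mean in':>9s} {'mean out':>9s}")
for rec in template:
    row = summary.loc[rec.analyte_id]
    print(
        f"{rec.analyte_id:22s} {rec.detection_frequency:8.2f} "
        f"{row['detection_frequency_pct']:9.2f} {rec.mean_concentration:9.3f} "
        f"{row['mean']:9.3f}"
    )

records = records_from_summary(summary.reset_index())
print(f"\nre-summarised records: {len(records)} — schema-compatible with the")
print("exposure/risk stages, so the full pipeline runs on purely synthetic data.")
print("At n = 86 the recovered frequencies and means scatter around the inputs")
print("with binomial / lognormal sampling error; at n = 5000 they converge.")
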