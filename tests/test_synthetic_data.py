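"""Hurdle-lognormal survey generator: determinism, censoring, recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from seafoodrisk import (
    AnalyteModel,
    SurveyConfig,
    generate_survey,
    records_from_summary,
    summarize_survey,
    survey_config_from_summary,
)
from seafoodrisk.reference_data import ValidationError
from seafoodrisk.synthetic_data import DEFAULT_SEASONS, write_survey_csv


def _model(**kw):
    defaults = dict(
        analyte_id="x", detection_p=0.6, mu=0.0, sigma=0.5, lod=1e-4
    )
    defaults.update(kw)
    return AnalyteModel(**defaults)


class TestGenerate:
    def test_fixed_seed_reproduces_byte_identical_output(self, tmp_path):
        config = SurveyConfig(analytes=[_model()], seed=42)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_survey_csv(generate_survey(config), a)
        write_survey_csv(generate_survey(config), b)
        assert a.read_bytes() == b.read_bytes()

    def test_degenerate_limit_concentrates_at_exp_mu(self):
        config = SurveyConfig(
            analytes=[_model(detection_p=1.0, mu=math.log(3.0), sigma=1e-9)],
            seed=0,
        )
        table = generate_survey(config)
        assert not table["nd"].any()
        assert np.allclose(table["value"], 3.0, rtol=1e-6)

    def test_detected_count_within_binomial_band(self):
        # 86 specimens at the most-frequent analyte's detection probability:
        # the detected count must sit inside the 95% binomial band over
        # 200 replicates (LOD far below the bulk, so censoring is negligible)
        p, n, reps = 0.6047, 86, 200
        counts = []
        for seed in range(reps):
            config = SurveyConfig(
                analytes=[_model(detection_p=p, mu=0.0, sigma=0.5, lod=1e-6)],
                seed=seed,
            )
            table = generate_survey(config)
            counts.append(int((~table["nd"]).sum()))
        mean_count = np.mean(counts)
        se = math.sqrt(n * p * (1 - p) / reps)
        assert abs(mean_count - n * p) < 1.96 * se

    def test_no_numeric_value_below_lod_marked_detected(self):
        config = SurveyConfig(
            analytes=[_model(mu=-2.0, sigma=1.5, lod=0.05)], seed=7
        )
        table = generate_survey(config)
        detected = table.loc[~table["nd"], "value"]
        assert (detected >= 0.05).all()
        assert table.loc[table["nd"], "value"].isna().all()

    def test_seasonal_layout_and_multipliers(self):
        config = SurveyConfig(
            analytes=[_model(detection_p=1.0, sigma=0.01, lod=1e-9)],
            seasonal_multipliers={"spring_2017": 10.0},
            seed=3,
        )
        table = generate_survey(config)
        assert table.groupby("season")["specimen_id"].nunique().sum() == 86
        spring = table.loc[table["season"] == "spring_2017", "value"].mean()
        rest = table.loc[table["season"] != "spring_2017", "value"].mean()
        assert spring > 5 * rest

    def test_invalid_config_rejected_before_generation(self):
        with pytest.raises(ValidationError):
            _model(detection_p=1.5)
        with pytest.raises(ValidationError):
            _model(sigma=0.0)
        with pytest.raises(ValidationError):
            SurveyConfig(analytes=[])


class TestSummarize:
    def test_all_detected_constant_value(self):
        table = pd.DataFrame(
            {
                "specimen_id": [f"S{i}" for i in range(5)],
                "season": ["s"] * 5,
                "analyte_id": ["x"] * 5,
                "value": [2.5] * 5,
                "nd": [False] * 5,
                "units": ["mg_per_kg"] * 5,
                "basis": ["wet"] * 5,
            }
        )
        summary = summarize_survey(table)
        row = summary.iloc[0]
        assert row["detection_frequency_pct"] == 100.0
        assert row["mean"] == 2.5 and row["sd"] == 0.0

    def test_none_detected_marked_nd(self):
        table = pd.DataFrame(
            {
                "specimen_id": ["S1", "S2"],
                "season": ["s", "s"],
                "analyte_id": ["x", "x"],
                "value": [np.nan, np.nan],
                "nd": [True, True],
                "units": ["mg_per_kg"] * 2,
                "basis": ["wet"] * 2,
            }
        )
        row = summarize_survey(table).iloc[0]
        assert row["detection_frequency_pct"] == 0.0
        assert bool(row["nd"])

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValidationError):
            summarize_survey(pd.DataFrame())

    def test_parameter_recovery_at_large_n(self):
        # frequency within 3 binomial SEs of p, detect-mean within 3 SEs of
        # the lognormal mean exp(µ + σ²/2), at 5,000 specimens
        p, mu, sigma, n = 0.6047, math.log(2.0), 0.6, 5000
        config = SurveyConfig(
            analytes=[_model(detection_p=p, mu=mu, sigma=sigma, lod=1e-6)],
            seasons=(("all", n),),
            seed=11,
        )
        table = generate_survey(config)
        summary = summarize_survey(table).iloc[0]
        freq_se = 100.0 * math.sqrt(p * (1 - p) / n)
        assert abs(summary["detection_frequency_pct"] - 100 * p) < 3 * freq_se
        true_mean = math.exp(mu + sigma**2 / 2)
        true_sd = true_mean * math.sqrt(math.exp(sigma**2) - 1)
        n_det = n * summary["detection_frequency_pct"] / 100.0
        mean_se = true_sd / math.sqrt(n_det)
        assert abs(summary["mean"] - true_mean) < 3 * mean_se

    def test_all_specimen_summary_includes_nd_as_zero(self):
        table = pd.DataFrame(
            {
                "specimen_id": ["S1", "S2"],
                "season": ["s", "s"],
                "analyte_id": ["x", "x"],
                "value": [4.0, np.nan],
                "nd": [False, True],
                "units": ["mg_per_kg"] * 2,
                "basis": ["wet"] * 2,
            }
        )
        detects = summarize_survey(table, summary="detects").iloc[0]
        everything = summarize_survey(table, summary="all").iloc[0]
        assert detects["mean"] == 4.0
        assert everything["mean"] == 2.0


class TestRoundTrip:
    def test_template_derived_survey_feeds_the_pipeline(self, ocp_records):
        config = survey_config_from_summary(ocp_records, seed=5)
        assert config.n_specimens == 86
        assert config.seasons == DEFAULT_SEASONS
        table = generate_survey(config)
        records = records_from_summary(summarize_survey(table))
        assert {r.analyte_id for r in records} == {r.analyte_id for r in ocp_records}
        # summarised records are schema-compatible with the exposure stage
        from seafoodrisk import ExposureScenario, convert_units, edi_ocp

        sc = ExposureScenario()
        for r in records:
            mg = convert_units(r, "mg_per_kg")
            assert edi_ocp(mg.mean_concentration, sc).edi >= 0

    def test_nd_template_analyte_never_detected(self, ocp_records):
        config = survey_config_from_summary(ocp_records, seed=5)
        table = generate_survey(config)
        ddt = table[table["analyte_id"] == "ddt"]
        assert ddt["nd"].all()
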