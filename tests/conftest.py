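import pytest

from seafoodrisk import (
    DEFAULT_ANALYTES,
    ExposureScenario,
    RiskConfig,
    build_registry,
    fixture_bundle,
    read_concentration_table,
    read_toxicity_table,
)


@pytest.fixture(scope="session")
def fixtures():
    """Paths to the bundled published-summary tables."""
    return fixture_bundle()


@pytest.fixture(scope="session")
def scenario():
    """Default consumption scenario (32.88 g/day, 74.3 kg, 26 y × 365 d/y)."""
    return ExposureScenario()


@pytest.fixture(scope="session")
def risk_config():
    return RiskConfig()


@pytest.fixture(scope="session")
def registry(fixtures):
    """Full registry: 27 analytes with the bundled toxicity references."""
    refs = read_toxicity_table(fixtures["table4_toxrefs.csv"]) + read_toxicity_table(
        fixtures["metal_toxrefs.csv"]
    )
    return build_registry(DEFAULT_ANALYTES, refs)


@pytest.fixture(scope="session")
def metal_records(fixtures):
    return read_concentration_table(fixtures["table1_tm.csv"])


@pytest.fixture(scope="session")
def ocp_records(fixtures):
    """OCP summary rows on their measurement scale (µg/kg wet)."""
    return read_concentration_table(fixtures["table1_ocp.csv"])


@pytest.fixture(scope="session")
def ocp_mg_records(fixtures):
    """OCP concentrations on the mg/kg scale used for dose arithmetic."""
    return read_concentration_table(fixtures["table4_ocp.csv"])
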