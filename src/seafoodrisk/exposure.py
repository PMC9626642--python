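"""Estimated daily intake (EDI) of tissue contaminants from fish consumption.

Two intake formulas are used, one per contaminant class:

* trace metals:  EDI = C × VIRd × (ED × EF) / (BW × AT)
* OCPs:          EDI = C × VIRd / BW

With the default averaging time AT = ED × EF the duration factor is exactly
1 and the two coincide. C is the tissue concentration in mg/kg, VIRd the
daily intake of fillet in g/day and BW the body weight in kg.

Two arithmetic modes are provided. ``paper_compat`` leaves VIRd as a bare
gram count, which is how the published report tables this package
reproduces were computed; the resulting numbers are 1000× larger than a
dimensionally coherent dose. ``strict_si`` applies the 10⁻³ g→kg factor and
yields EDI in mg per kg body weight per day. The mode is carried on the
result so downstream consumers know which convention they hold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .reference_data import (
    ConcentrationRecord,
    ExposureScenario,
    Registry,
    ValidationError,
)

__all__ = ["ExposureResult", "edi_ocp", "edi_tm", "edi_batch"]

#: units token per mode — paper_compat values are numerically
#: C[mg/kg] × VIR[g/day] / BW[kg]; strict_si values are true doses.
_UNIT_TOKENS = {
    "paper_compat": "(mg/kg)*(g/day)/kg",
    "strict_si": "mg/kg-bw/day",
}


@dataclass(frozen=True)
class ExposureResult:
    """Per-analyte estimated daily intake."""

    analyte_id: str
    edi: float
    edi_units: str
    mode: str


def _mode_factor(mode: str) -> float:
    return 1e-3 if mode == "strict_si" else 1.0


def edi_ocp(
    concentration: float,
    scenario: ExposureScenario,
    analyte_id: str = "",
) -> ExposureResult:
    """Daily intake of an OCP: C × VIRd / BW (concentration in mg/kg)."""
    if concentration < 0:
        raise ValidationError(f"negative concentration {concentration}")
    value = concentration * scenario.vir_d / scenario.bw * _mode_factor(scenario.mode)
    return ExposureResult(analyte_id, value, _UNIT_TOKENS[scenario.mode], scenario.mode)


def edi_tm(
    concentration: float,
    scenario: ExposureScenario,
    analyte_id: str = "",
) -> ExposureResult:
    """Daily intake of a trace metal: C × VIRd × (ED×EF)/AT / BW.

    With the default AT = ED × EF the duration factor is 1 and this is
    numerically identical to :func:`edi_ocp`.
    """
    if concentration < 0:
        raise ValidationError(f"negative concentration {concentration}")
    value = (
        concentration
        * scenario.vir_d
        * scenario.duration_factor
        / scenario.bw
        * _mode_factor(scenario.mode)
    )
    return ExposureResult(analyte_id, value, _UNIT_TOKENS[scenario.mode], scenario.mode)


def edi_batch(
    records: Sequence[ConcentrationRecord],
    scenario: ExposureScenario,
    registry: Registry,
) -> list[ExposureResult]:
    """Intake for every record, dispatching on contaminant class.

    All records must already be unit-normalised to mg/kg; mixed or
    unsupported units abort before any computation. Ordering is preserved.
    """
    bad = [r.analyte_id for r in records if r.units != "mg_per_kg"]
    if bad:
        raise ValidationError(
            f"records not in mg_per_kg: {', '.join(bad)} — convert units first"
        )
    results: list[ExposureResult] = []
    for record in records:
        analyte = registry.analyte(record.analyte_id)
        if analyte is None:
            raise ValidationError(f"unknown analyte id {record.analyte_id!r}")
        fn = edi_tm if analyte.contaminant_class == "trace_metal" else edi_ocp
        results.append(fn(record.mean_concentration, scenario, record.analyte_id))
    return results
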