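"""Non-carcinogenic and carcinogenic risk indices for tissue contaminants.

Implemented indices
-------------------
* **THQ** (target hazard quotient, trace metals)::

      THQ = (EF × ED × VIRd × C) / (RfD × BW × AT) × 10⁻³

  The 10⁻³ is the g→kg conversion of the intake rate, applied exactly once;
  the denominator is the product RfD × BW × AT (the only dimensionally
  coherent form). THQ > 1 flags potential non-cancer effects.

* **HI** (hazard index): Σ THQ over metals, assuming additive effects.

* **HQ** (OCP hazard quotient): 100 × EDI / RfD, with concern threshold
  100; **ΣHQ** is its sum over OCPs.

* **ILCR** (incremental lifetime cancer risk): EDI × CSF; probabilities
  above 1×10⁻⁶ are conventionally flagged.

* **CR_lim** (maximum allowable consumption rate, kg/day)::

      CR_lim = ARL × BW / Σ (C_m × CSF_m)

  computed per analyte by default, or pooled over an analyte set.

* **MRL screening**: mean concentration strictly above the upper maximum
  residue level bound, with the fold-change.

Quantities that cannot be computed (missing RfD or CSF) yield the explicit
``NOT_COMPUTABLE`` marker — never a silent zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .exposure import ExposureResult, edi_ocp, edi_tm
from .reference_data import (
    ConcentrationRecord,
    ExposureScenario,
    Registry,
    RiskConfig,
    ToxicityReference,
    ValidationError,
)

__all__ = [
    "NOT_COMPUTABLE",
    "RiskResult",
    "AggregateRisk",
    "HazardSum",
    "CrLim",
    "MrlScreen",
    "thq_tm",
    "hazard_index",
    "hq_ocp",
    "total_hq",
    "ilcr",
    "cr_lim",
    "cr_lim_single",
    "mrl_screen",
    "safe_consumption_rate",
    "compute_risk",
    "MEAL_SIZE_G",
]

#: reference meal size (g) used to express allowable consumption in meals/day
MEAL_SIZE_G = 32.88


class _NotComputable:
    """Marker for a quantity whose toxicity benchmark is absent."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NOT_COMPUTABLE"

    def __bool__(self) -> bool:
        return False


NOT_COMPUTABLE = _NotComputable()


def _is_number(x) -> bool:
    return isinstance(x, (int, float)) and not isinstance(x, bool)


def _edi_value(edi: ExposureResult | float) -> float:
    return edi.edi if isinstance(edi, ExposureResult) else float(edi)


# ---------------------------------------------------------------------------
# Non-carcinogenic indices

def thq_tm(
    concentration: float,
    rfd: float | None,
    scenario: ExposureScenario,
):
    """Target hazard quotient of a trace metal (dimensionless).

    ``concentration`` in mg/kg, ``rfd`` in mg/kg-bw/day. Absent RfD returns
    the NOT_COMPUTABLE marker.
    """
    if rfd is None:
        return NOT_COMPUTABLE
    if rfd <= 0:
        raise ValidationError(f"RfD must be positive, got {rfd}")
    if concentration < 0:
        raise ValidationError(f"negative concentration {concentration}")
    return (
        scenario.ef
        * scenario.ed
        * scenario.vir_d
        * concentration
        / (rfd * scenario.bw * scenario.at)
        * 1e-3
    )


@dataclass(frozen=True)
class HazardSum:
    """A hazard aggregate with its contributor breakdown.

    ``partial`` is True when any contributor was not computable; the ids of
    skipped contributors are listed so silence never hides a gap.
    """

    value: float
    contributors: Mapping[str, float]
    partial: bool = False
    skipped: tuple[str, ...] = ()


def _aggregate(values, label: str) -> HazardSum:
    if isinstance(values, Mapping):
        items = list(values.items())
    else:
        items = [(f"{label}_{i}", v) for i, v in enumerate(values)]
    computable = {k: v for k, v in items if _is_number(v)}
    skipped = tuple(k for k, v in items if not _is_number(v))
    for k, v in computable.items():
        if not math.isfinite(v) or v < 0:
            raise ValidationError(f"{k}: contribution {v} is not finite and >= 0")
    return HazardSum(
        value=math.fsum(computable.values()),
        contributors=computable,
        partial=bool(skipped),
        skipped=skipped,
    )


def hazard_index(thqs) -> HazardSum:
    """Hazard index HI = Σ THQ (exact sum, with contributor breakdown)."""
    return _aggregate(thqs, "thq")


def hq_ocp(edi: ExposureResult | float, rfd: float | None):
    """OCP hazard quotient HQ = 100 × EDI / RfD (threshold of concern: 100)."""
    if rfd is None:
        return NOT_COMPUTABLE
    if rfd <= 0:
        raise ValidationError(f"RfD must be positive, got {rfd}")
    return 100.0 * _edi_value(edi) / rfd


def total_hq(hqs) -> HazardSum:
    """ΣHQ over OCPs (exact sum, with contributor breakdown)."""
    return _aggregate(hqs, "hq")


# ---------------------------------------------------------------------------
# Carcinogenic indices

def ilcr(edi: ExposureResult | float, csf: float | None):
    """Incremental lifetime cancer risk: EDI × CSF."""
    if csf is None:
        return NOT_COMPUTABLE
    if csf <= 0:
        raise ValidationError(f"CSF must be positive, got {csf}")
    return _edi_value(edi) * csf


@dataclass(frozen=True)
class CrLim:
    """Maximum allowable consumption rate at the acceptable risk level."""

    kg_per_day: float
    g_per_day: float
    meals_per_day: float

    @classmethod
    def from_kg(cls, kg: float, meal_size_g: float = MEAL_SIZE_G) -> "CrLim":
        return cls(kg, kg * 1e3, kg * 1e3 / meal_size_g)


def cr_lim_single(
    concentration: float,
    csf: float,
    arl: float = 1e-5,
    bw: float = 74.3,
) -> CrLim:
    """CR_lim for one analyte: ARL × BW / (C × CSF), in kg/day."""
    denom = concentration * csf
    if denom == 0:
        return CrLim.from_kg(math.inf)
    return CrLim.from_kg(arl * bw / denom)


def cr_lim(
    records: Sequence[ConcentrationRecord],
    registry: Registry,
    arl: float = 1e-5,
    bw: float = 74.3,
    pooled: bool = False,
):
    """Maximum allowable consumption rate over a record set.

    Per-analyte by default (a dict id → :class:`CrLim`, with the
    NOT_COMPUTABLE marker where the slope factor is absent); ``pooled=True``
    sums C × CSF over every record with a slope factor and returns a single
    :class:`CrLim`. A zero Σ(C×CSF) yields an infinite-allowance marker,
    never a division error. Concentrations must be in mg/kg.
    """
    bad = [r.analyte_id for r in records if r.units != "mg_per_kg"]
    if bad:
        raise ValidationError(f"records not in mg_per_kg: {', '.join(bad)}")
    if pooled:
        total = math.fsum(
            r.mean_concentration * ref.csf
            for r in records
            if (ref := registry.reference(r.analyte_id)) is not None
            and ref.csf is not None
        )
        return CrLim.from_kg(math.inf) if total == 0 else CrLim.from_kg(arl * bw / total)
    out: dict[str, CrLim | _NotComputable] = {}
    for r in records:
        ref = registry.reference(r.analyte_id)
        if ref is None or ref.csf is None:
            out[r.analyte_id] = NOT_COMPUTABLE
        else:
            out[r.analyte_id] = cr_lim_single(r.mean_concentration, ref.csf, arl, bw)
    return out


# ---------------------------------------------------------------------------
# MRL screening

@dataclass(frozen=True)
class MrlScreen:
    """Result of screening a mean concentration against the upper MRL bound."""

    exceeds: bool
    fold: float
    mrl_high: float


def mrl_screen(
    record: ConcentrationRecord, reference: ToxicityReference
) -> MrlScreen:
    """Exceedance iff mean > mrl_high (strict); fold = mean / mrl_high.

    The MRL must be expressed on the record's units and basis — there is no
    silent conversion.
    """
    if reference.mrl_high is None:
        raise ValidationError(f"{record.analyte_id}: no MRL upper bound available")
    expected = f"{record.units}_{record.basis}"
    if reference.mrl_units != expected:
        raise ValidationError(
            f"{record.analyte_id}: MRL units {reference.mrl_units!r} do not match "
            f"record units/basis {expected!r}"
        )
    fold = record.mean_concentration / reference.mrl_high
    return MrlScreen(
        exceeds=record.mean_concentration > reference.mrl_high,
        fold=fold,
        mrl_high=reference.mrl_high,
    )


# ---------------------------------------------------------------------------
# Safe-consumption inversion

def safe_consumption_rate(
    concentration: float,
    reference: ToxicityReference,
    scenario: ExposureScenario,
    threshold_kind: str = "thq",
    config: RiskConfig | None = None,
) -> float:
    """Intake rate (g/day) at which the chosen index sits exactly at its threshold.

    ``threshold_kind``: ``thq`` (metal THQ = 1), ``hq`` (OCP HQ = 100) or
    ``ilcr`` (ILCR = 1e-6). All three indices are linear in VIRd, so the
    inversion is the closed form VIR* = VIRd × threshold / index(VIRd).
    Zero concentration gives an infinite allowance.
    """
    config = config or RiskConfig()
    if concentration < 0:
        raise ValidationError(f"negative concentration {concentration}")
    if concentration == 0:
        return math.inf
    if threshold_kind == "thq":
        base, threshold = thq_tm(concentration, reference.rfd, scenario), config.thq_threshold_tm
    elif threshold_kind == "hq":
        base = hq_ocp(edi_ocp(concentration, scenario), reference.rfd)
        threshold = config.hq_threshold_ocp
    elif threshold_kind == "ilcr":
        base = ilcr(edi_tm(concentration, scenario), reference.csf)
        threshold = config.ilcr_threshold
    else:
        raise ValidationError(f"unknown threshold_kind {threshold_kind!r}")
    if base is NOT_COMPUTABLE:
        raise ValidationError(
            f"{reference.analyte_id}: toxicity benchmark for {threshold_kind} absent"
        )
    return scenario.vir_d * threshold / base


# ---------------------------------------------------------------------------
# Batch computation

@dataclass(frozen=True)
class RiskResult:
    """All risk indices for one analyte (markers where not computable)."""

    analyte_id: str
    contaminant_class: str
    edi: float
    thq: float | _NotComputable = NOT_COMPUTABLE
    hq: float | _NotComputable = NOT_COMPUTABLE
    ilcr: float | _NotComputable = NOT_COMPUTABLE
    cr_lim_kg_day: float | _NotComputable = NOT_COMPUTABLE
    exceeds_mrl: bool | None = None
    fold_mrl: float | None = None
    flags: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class AggregateRisk:
    """HI over metals and ΣHQ over OCPs, with the scenario echoed."""

    hi: HazardSum
    thq_total: HazardSum
    scenario: ExposureScenario


def compute_risk(
    records: Sequence[ConcentrationRecord],
    registry: Registry,
    scenario: ExposureScenario,
    config: RiskConfig | None = None,
    screening_records: Sequence[ConcentrationRecord] | None = None,
) -> tuple[list[RiskResult], AggregateRisk]:
    """Full per-analyte risk table plus aggregates.

    ``records`` must be unit-normalised to mg/kg. MRL screening compares
    against the (possibly differently scaled) ``screening_records`` when
    given — MRLs are published on the measurement units/basis, so screening
    happens there, while dose arithmetic happens in mg/kg.
    """
    config = config or RiskConfig()
    screening = {r.analyte_id: r for r in (screening_records or records)}
    results: list[RiskResult] = []
    thqs: dict[str, float] = {}
    hqs: dict[str, float] = {}
    for record in records:
        analyte = registry.analyte(record.analyte_id)
        if analyte is None:
            raise ValidationError(f"unknown analyte id {record.analyte_id!r}")
        ref = registry.reference(record.analyte_id)
        rfd = ref.rfd if ref else None
        csf = ref.csf if ref else None
        notes: list[str] = []
        flags: list[str] = []
        is_metal = analyte.contaminant_class == "trace_metal"
        if is_metal:
            exposure = edi_tm(record.mean_concentration, scenario, record.analyte_id)
            thq = thq_tm(record.mean_concentration, rfd, scenario)
            hq = NOT_COMPUTABLE
            thqs[record.analyte_id] = thq
            if thq is NOT_COMPUTABLE:
                notes.append("THQ not computable: RfD absent")
            elif thq > config.thq_threshold_tm:
                flags.append(f"THQ>{config.thq_threshold_tm:g}")
        else:
            exposure = edi_ocp(record.mean_concentration, scenario, record.analyte_id)
            hq = hq_ocp(exposure, rfd)
            thq = NOT_COMPUTABLE
            hqs[record.analyte_id] = hq
            if hq is NOT_COMPUTABLE:
                notes.append("HQ not computable: RfD absent")
            elif hq > config.hq_threshold_ocp:
                flags.append(f"HQ>{config.hq_threshold_ocp:g}")
        cancer = ilcr(exposure, csf)
        if cancer is NOT_COMPUTABLE:
            notes.append("ILCR not computable: CSF absent")
        elif cancer > config.ilcr_threshold:
            flags.append(f"ILCR>{config.ilcr_threshold:g}")
        if csf is not None:
            limit = cr_lim_single(
                record.mean_concentration, csf, config.arl, scenario.bw
            ).kg_per_day
        else:
            limit = NOT_COMPUTABLE
            notes.append("CR_lim not computable: CSF absent")
        exceeds: bool | None = None
        fold: float | None = None
        if ref is not None and ref.mrl_high is not None:
            screen_rec = screening.get(record.analyte_id, record)
            try:
                screen = mrl_screen(screen_rec, ref)
            except ValidationError as exc:
                notes.append(f"MRL screen skipped: {exc}")
            else:
                exceeds, fold = screen.exceeds, screen.fold
                if screen.exceeds:
                    flags.append("MRL exceeded")
        else:
            notes.append("MRL screen skipped: no MRL upper bound")
        results.append(
            RiskResult(
                analyte_id=record.analyte_id,
                contaminant_class=analyte.contaminant_class,
                edi=exposure.edi,
                thq=thq,
                hq=hq,
                ilcr=cancer,
                cr_lim_kg_day=limit,
                exceeds_mrl=exceeds,
                fold_mrl=fold,
                flags=tuple(flags),
                notes=tuple(notes),
            )
        )
    aggregate = AggregateRisk(
        hi=hazard_index(thqs), thq_total=total_hq(hqs), scenario=scenario
    )
    return results, aggregate
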