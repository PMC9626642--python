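"""Domain types, unit handling and readers for contaminant monitoring tables.

The package works from three plain-text inputs:

* a concentration table — one row per analyte with the detection frequency,
  mean ± SD of the tissue concentration, units (mg/kg or µg/kg) and the
  dry/wet basis it was measured on;
* a toxicity-reference table — per-analyte oral reference dose (RfD),
  cancer slope factor (CSF/OSF) and maximum residue level (MRL) range,
  each with a provenance citation;
* an exposure-scenario config — daily intake rate, body weight, exposure
  duration/frequency and averaging time.

Everything downstream (exposure, risk, source diagnostics) consumes the
types defined here.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from decimal import Decimal
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "Analyte",
    "ConcentrationRecord",
    "ExposureScenario",
    "ToxicityReference",
    "RiskConfig",
    "Registry",
    "SchemaError",
    "ValidationError",
    "UnsupportedConversionError",
    "DEFAULT_ANALYTES",
    "read_concentration_table",
    "write_concentration_table",
    "read_toxicity_table",
    "read_scenario",
    "convert_units",
    "convert_basis",
    "build_registry",
    "resolve_nd",
]

ND_TOKEN = "ND"

CONCENTRATION_COLUMNS = [
    "analyte_id",
    "class",
    "family",
    "mean",
    "sd",
    "detection_frequency_pct",
    "n",
    "units",
    "basis",
    "season",
    "nd",
]

TOXICITY_COLUMNS = [
    "analyte_id",
    "rfd_mg_kg_day",
    "csf_per_mg_kg_day",
    "mrl_low",
    "mrl_high",
    "mrl_units",
    "provenance",
]

VALID_UNITS = ("mg_per_kg", "ug_per_kg")
VALID_BASES = ("dry", "wet")
VALID_CLASSES = ("trace_metal", "ocp")
VALID_FAMILIES = ("DDx", "HCH", "chlordane", "drin", "endosulfan", "none")
VALID_ND_POLICIES = ("zero", "half_lod", "lod")
VALID_MODES = ("paper_compat", "strict_si")


class SchemaError(ValueError):
    """An input file does not match the documented column schema."""


class ValidationError(ValueError):
    """A field value violates a domain invariant."""


class UnsupportedConversionError(ValueError):
    """A unit/basis conversion that needs information not supplied."""


@dataclass(frozen=True)
class Analyte:
    """One measured contaminant: a trace metal or an organochlorine pesticide.

    ``family`` groups OCPs into the chemical families used for isomer /
    metabolite composition diagnostics; trace metals carry ``family='none'``.
    ``technical_profile`` optionally records the manufactured isomer
    composition (mass fractions summing to 1) of the technical product.
    """

    id: str
    name: str
    contaminant_class: str
    family: str = "none"
    technical_profile: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.contaminant_class not in VALID_CLASSES:
            raise ValidationError(
                f"{self.id}: contaminant_class must be one of {VALID_CLASSES}"
            )
        if self.family not in VALID_FAMILIES:
            raise ValidationError(f"{self.id}: unknown family {self.family!r}")
        if self.contaminant_class == "trace_metal" and self.family != "none":
            raise ValidationError(f"{self.id}: trace metals must have family='none'")
        if self.technical_profile is not None:
            total = math.fsum(self.technical_profile.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"{self.id}: technical_profile fractions sum to {total}, not 1"
                )


@dataclass(frozen=True)
class ConcentrationRecord:
    """One analyte's tissue-concentration summary (one row of the table).

    ``nd_flag`` marks analytes whose mean was below the limit of detection;
    the numeric value stored for such rows follows the nd-policy chosen at
    read time (0 under the default ``zero`` policy).
    """

    analyte_id: str
    mean_concentration: float
    sd: float | None = None
    detection_frequency: float = 100.0
    n_samples: int | None = None
    units: str = "mg_per_kg"
    basis: str = "wet"
    season: str | None = None
    nd_flag: bool = False

    def __post_init__(self) -> None:
        if self.mean_concentration < 0:
            raise ValidationError(
                f"{self.analyte_id}: negative concentration {self.mean_concentration}"
            )
        if self.sd is not None and self.sd < 0:
            raise ValidationError(f"{self.analyte_id}: negative SD {self.sd}")
        if not 0.0 <= self.detection_frequency <= 100.0:
            raise ValidationError(
                f"{self.analyte_id}: detection frequency {self.detection_frequency} "
                "outside [0, 100]"
            )
        if self.n_samples is not None and self.n_samples <= 0:
            raise ValidationError(f"{self.analyte_id}: n_samples must be positive")
        if self.units not in VALID_UNITS:
            raise ValidationError(f"{self.analyte_id}: unknown units {self.units!r}")
        if self.basis not in VALID_BASES:
            raise ValidationError(f"{self.analyte_id}: unknown basis {self.basis!r}")


@dataclass(frozen=True)
class ExposureScenario:
    """Point-estimate consumption scenario.

    Defaults are the Mexican adult scenario: 32.88 g/day of fish fillet at
    74.3 kg body weight, 26 years of exposure at 365 days/year, averaged
    over the exposure period (so EF×ED/AT = 1).

    ``mode`` selects the arithmetic convention: ``paper_compat`` keeps the
    intake rate as a bare gram count (reproducing published report tables
    that skip the g→kg step), ``strict_si`` applies the 10⁻³ g→kg factor so
    intakes come out in mg per kg body weight per day.
    """

    vir_d: float = 32.88
    bw: float = 74.3
    ed: float = 26.0
    ef: float = 365.0
    at: float | None = None
    mode: str = "paper_compat"

    def __post_init__(self) -> None:
        if self.at is None:
            object.__setattr__(self, "at", self.ef * self.ed)
        for name in ("vir_d", "bw", "ed", "ef", "at"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"scenario parameter {name} must be positive")
        if self.mode not in VALID_MODES:
            raise ValidationError(f"unknown scenario mode {self.mode!r}")

    @property
    def duration_factor(self) -> float:
        """(ED × EF) / AT — equals 1 under the default averaging time."""
        return (self.ed * self.ef) / self.at


@dataclass(frozen=True)
class ToxicityReference:
    """Per-analyte toxicity benchmarks: RfD, cancer slope factor, MRL range.

    All doses in mg per kg body weight per day; the MRL range is carried in
    ``mrl_units`` (a combined units+basis token such as ``mg_per_kg_dry``)
    and is only comparable to concentrations on the same units and basis.
    """

    analyte_id: str
    rfd: float | None = None
    csf: float | None = None
    mrl_low: float | None = None
    mrl_high: float | None = None
    mrl_units: str | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.rfd is not None and self.rfd <= 0:
            raise ValidationError(f"{self.analyte_id}: RfD must be > 0 when present")
        if self.csf is not None and self.csf <= 0:
            raise ValidationError(f"{self.analyte_id}: CSF must be > 0 when present")
        if (
            self.mrl_low is not None
            and self.mrl_high is not None
            and self.mrl_low > self.mrl_high
        ):
            raise ValidationError(
                f"{self.analyte_id}: mrl_low {self.mrl_low} > mrl_high {self.mrl_high}"
            )


@dataclass(frozen=True)
class RiskConfig:
    """Thresholds and conventions for the risk stage.

    * ``arl`` — acceptable lifetime cancer-risk level used by the maximum
      allowable consumption rate (default 1e-5);
    * ``thq_threshold_tm`` — THQ concern threshold for trace metals (1);
    * ``hq_threshold_ocp`` — HQ concern threshold for OCPs (100, because the
      OCP quotient is defined as 100 × EDI/RfD);
    * ``ilcr_threshold`` — lifetime cancer-risk probability above which an
      analyte is flagged (1e-6);
    * ``nd_policy`` — substitution rule for below-LOD means.
    """

    arl: float = 1e-5
    thq_threshold_tm: float = 1.0
    hq_threshold_ocp: float = 100.0
    ilcr_threshold: float = 1e-6
    nd_policy: str = "zero"
    report_precision: Mapping[str, int] = field(
        default_factory=lambda: {
            "edi": 4,
            "thq": 2,
            "hq": 2,
            "ilcr": 6,
            "cr_lim_kg_day": 4,
            "fold_mrl": 1,
        }
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.arl < 1.0:
            raise ValidationError(f"arl {self.arl} outside (0, 1)")
        for name in ("thq_threshold_tm", "hq_threshold_ocp", "ilcr_threshold"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")
        if self.nd_policy not in VALID_ND_POLICIES:
            raise ValidationError(f"unknown nd_policy {self.nd_policy!r}")


def resolve_nd(nd_policy: str, lod: float | None) -> float:
    """Numeric value substituted for a below-LOD mean under ``nd_policy``."""
    if nd_policy == "zero":
        return 0.0
    if lod is None:
        raise ValidationError(
            f"nd_policy={nd_policy!r} needs a limit of detection, none supplied"
        )
    return lod / 2.0 if nd_policy == "half_lod" else lod


# ---------------------------------------------------------------------------
# Default analyte registry: the 7 trace metals and 20 OCPs of the survey,
# with family membership and technical-mixture profiles where the product
# composition is known (endosulfan 70:30 I:II).

DEFAULT_ANALYTES: tuple[Analyte, ...] = (
    Analyte("cd", "Cd", "trace_metal"),
    Analyte("cu", "Cu", "trace_metal"),
    Analyte("fe", "Fe", "trace_metal"),
    Analyte("mn", "Mn", "trace_metal"),
    Analyte("ni", "Ni", "trace_metal"),
    Analyte("pb", "Pb", "trace_metal"),
    Analyte("zn", "Zn", "trace_metal"),
    Analyte("aldrin", "Aldrin", "ocp", "drin"),
    Analyte("ddd", "p,p'-DDD", "ocp", "DDx"),
    Analyte("dde", "p,p'-DDE", "ocp", "DDx"),
    Analyte("ddt", "p,p'-DDT", "ocp", "DDx"),
    Analyte("dieldrin", "Dieldrin", "ocp", "drin"),
    Analyte(
        "endosulfan_i",
        "Endosulfan I",
        "ocp",
        "endosulfan",
        technical_profile={"endosulfan_i": 0.70, "endosulfan_ii": 0.30},
    ),
    Analyte("endosulfan_ii", "Endosulfan II", "ocp", "endosulfan"),
    Analyte("endosulfan_sulfate", "Endosulfan sulfate", "ocp", "endosulfan"),
    Analyte("endrin", "Endrin", "ocp", "drin"),
    Analyte("endrin_aldehyde", "Endrin aldehyde", "ocp", "drin"),
    Analyte("endrin_ketone", "Endrin ketone", "ocp", "drin"),
    Analyte("heptachlor", "Heptachlor", "ocp", "chlordane"),
    Analyte("heptachlor_epoxide", "Heptachlor epoxide", "ocp", "chlordane"),
    Analyte("methoxychlor", "Methoxychlor", "ocp"),
    Analyte("alpha_hch", "alpha-HCH", "ocp", "HCH"),
    Analyte("beta_hch", "beta-HCH", "ocp", "HCH"),
    Analyte("gamma_hch", "gamma-HCH (lindane)", "ocp", "HCH"),
    Analyte("delta_hch", "delta-HCH", "ocp", "HCH"),
    Analyte("alpha_chlordane", "alpha-Chlordane", "ocp", "chlordane"),
    Analyte("gamma_chlordane", "gamma-Chlordane", "ocp", "chlordane"),
)


class Registry:
    """Keyed lookup pairing analytes with their toxicity references.

    Lookup is total: every id resolves either to the stored object or to an
    explicit ``None`` (absent marker) — defaults are never silently
    substituted.
    """

    def __init__(
        self,
        analytes: Sequence[Analyte],
        references: Sequence[ToxicityReference] = (),
    ) -> None:
        ids = [a.id for a in analytes]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValidationError(f"duplicate analyte ids: {', '.join(dupes)}")
        ref_ids = [r.analyte_id for r in references]
        ref_dupes = sorted({i for i in ref_ids if ref_ids.count(i) > 1})
        if ref_dupes:
            raise ValidationError(f"duplicate reference ids: {', '.join(ref_dupes)}")
        self._analytes = {a.id: a for a in analytes}
        self._references = {r.analyte_id: r for r in references}

    def __len__(self) -> int:
        return len(self._analytes)

    def __contains__(self, analyte_id: str) -> bool:
        return analyte_id in self._analytes

    def ids(self) -> list[str]:
        return list(self._analytes)

    def analyte(self, analyte_id: str) -> Analyte | None:
        return self._analytes.get(analyte_id)

    def reference(self, analyte_id: str) -> ToxicityReference | None:
        return self._references.get(analyte_id)

    def family_members(self, family: str) -> list[Analyte]:
        return [a for a in self._analytes.values() if a.family == family]


def build_registry(
    analytes: Sequence[Analyte],
    references: Sequence[ToxicityReference] = (),
) -> Registry:
    """Build a :class:`Registry`; duplicate ids raise listing the duplicates."""
    return Registry(analytes, references)


# ---------------------------------------------------------------------------
# Unit handling

_UNIT_EXPONENTS = {
    ("mg_per_kg", "ug_per_kg"): 3,
    ("ug_per_kg", "mg_per_kg"): -3,
}


def _shift_decimal(value: float, exponent: int) -> float:
    # Scaling by 10^±3 as a decimal-point shift: exact (round-trip identity)
    # for every value carrying a short decimal representation, i.e. anything
    # parsed from a data file. Plain float multiplication loses the last ulp
    # on ~2 % of inputs.
    return float(Decimal(repr(float(value))).scaleb(exponent))


def convert_units(
    record: ConcentrationRecord, target_units: str
) -> ConcentrationRecord:
    """Rescale a record between mg/kg and µg/kg (exact factor-of-1000 shift).

    Implemented as a decimal-point shift so converting there and back
    restores the stored value exactly. Basis is untouched; converting
    dry↔wet requires a moisture factor and is handled by
    :func:`convert_basis`.
    """
    if target_units not in VALID_UNITS:
        raise UnsupportedConversionError(f"unknown target units {target_units!r}")
    if record.units == target_units:
        return record
    exponent = _UNIT_EXPONENTS[(record.units, target_units)]
    return replace(
        record,
        mean_concentration=_shift_decimal(record.mean_concentration, exponent),
        sd=None if record.sd is None else _shift_decimal(record.sd, exponent),
        units=target_units,
    )


def convert_basis(
    record: ConcentrationRecord,
    target_basis: str,
    moisture_fraction: float | None = None,
) -> ConcentrationRecord:
    """Convert dry↔wet basis given the tissue moisture fraction.

    C_wet = C_dry × (1 − moisture); requesting a basis change without a
    moisture fraction is an error (no moisture content is ever invented).
    """
    if target_basis not in VALID_BASES:
        raise UnsupportedConversionError(f"unknown basis {target_basis!r}")
    if record.basis == target_basis:
        return record
    if moisture_fraction is None:
        raise UnsupportedConversionError(
            "dry/wet conversion requested without a moisture fraction"
        )
    if not 0.0 < moisture_fraction < 1.0:
        raise ValidationError(f"moisture fraction {moisture_fraction} outside (0,1)")
    dry_to_wet = 1.0 - moisture_fraction
    factor = dry_to_wet if target_basis == "wet" else 1.0 / dry_to_wet
    return replace(
        record,
        mean_concentration=record.mean_concentration * factor,
        sd=None if record.sd is None else record.sd * factor,
        basis=target_basis,
    )


# ---------------------------------------------------------------------------
# Readers / writers

def _parse_optional_float(cell: str) -> float | None:
    cell = cell.strip()
    if cell in ("", "NA", "NaN"):
        return None
    return float(cell)


def read_concentration_table(
    path: str | Path,
    nd_policy: str = "zero",
    lod: float | None = None,
) -> list[ConcentrationRecord]:
    """Read a concentration CSV into records.

    Rows whose ``mean`` is the literal ``ND`` (or whose ``nd`` column is
    true) get ``nd_flag=True`` and a mean substituted per ``nd_policy``.
    Missing required columns raise :class:`SchemaError` naming the column;
    a negative concentration raises :class:`ValidationError` with its row
    number.
    """
    path = Path(path)
    records: list[ConcentrationRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CONCENTRATION_COLUMNS if c not in header]
        if missing:
            raise SchemaError(
                f"{path.name}: missing required column(s): {', '.join(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            mean_cell = row["mean"].strip()
            nd_cell = row["nd"].strip().lower()
            nd_flag = mean_cell.upper() == ND_TOKEN or nd_cell in ("true", "1", "yes")
            if nd_flag:
                mean = resolve_nd(nd_policy, lod)
            else:
                mean = float(mean_cell)
                if mean < 0:
                    raise ValidationError(
                        f"{path.name} row {lineno}: negative concentration {mean}"
                    )
            sd_cell = row["sd"].strip()
            sd = None if (nd_flag and sd_cell.upper() == ND_TOKEN) else _parse_optional_float(sd_cell)
            n_cell = row["n"].strip()
            records.append(
                ConcentrationRecord(
                    analyte_id=row["analyte_id"].strip(),
                    mean_concentration=mean,
                    sd=sd,
                    detection_frequency=float(row["detection_frequency_pct"] or 100.0),
                    n_samples=int(n_cell) if n_cell else None,
                    units=row["units"].strip(),
                    basis=row["basis"].strip(),
                    season=row["season"].strip() or None,
                    nd_flag=nd_flag,
                )
            )
    return records


def analytes_from_table(path: str | Path) -> list[Analyte]:
    """Extract the analyte metadata (id, class, family) from a concentration CSV."""
    path = Path(path)
    seen: dict[str, Analyte] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in ("analyte_id", "class", "family") if c not in header]
        if missing:
            raise SchemaError(
                f"{path.name}: missing required column(s): {', '.join(missing)}"
            )
        for row in reader:
            aid = row["analyte_id"].strip()
            if aid not in seen:
                seen[aid] = Analyte(
                    id=aid,
                    name=aid,
                    contaminant_class=row["class"].strip(),
                    family=row["family"].strip() or "none",
                )
    return list(seen.values())


def write_concentration_table(
    records: Sequence[ConcentrationRecord], path: str | Path
) -> None:
    """Write records back to the documented CSV schema (read→write round-trips)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CONCENTRATION_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.analyte_id,
                    "",
                    "",
                    ND_TOKEN if r.nd_flag else repr(r.mean_concentration),
                    "" if r.sd is None else repr(r.sd),
                    repr(r.detection_frequency),
                    "" if r.n_samples is None else r.n_samples,
                    r.units,
                    r.basis,
                    r.season or "",
                    "true" if r.nd_flag else "false",
                ]
            )


def read_toxicity_table(path: str | Path) -> list[ToxicityReference]:
    """Read a toxicity-reference CSV (RfD, CSF, MRL range, provenance)."""
    path = Path(path)
    refs: list[ToxicityReference] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in TOXICITY_COLUMNS if c not in header]
        if missing:
            raise SchemaError(
                f"{path.name}: missing required column(s): {', '.join(missing)}"
            )
        for row in reader:
            refs.append(
                ToxicityReference(
                    analyte_id=row["analyte_id"].strip(),
                    rfd=_parse_optional_float(row["rfd_mg_kg_day"]),
                    csf=_parse_optional_float(row["csf_per_mg_kg_day"]),
                    mrl_low=_parse_optional_float(row["mrl_low"]),
                    mrl_high=_parse_optional_float(row["mrl_high"]),
                    mrl_units=row["mrl_units"].strip() or None,
                    provenance=row["provenance"].strip(),
                )
            )
    return refs


def read_scenario(path: str | Path) -> tuple[ExposureScenario, RiskConfig]:
    """Read a YAML scenario config into (ExposureScenario, RiskConfig)."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    scenario = ExposureScenario(
        vir_d=float(raw.get("vir_d_g_per_day", 32.88)),
        bw=float(raw.get("bw_kg", 74.3)),
        ed=float(raw.get("ed_years", 26)),
        ef=float(raw.get("ef_days_per_year", 365)),
        at=float(raw["at_days"]) if raw.get("at_days") is not None else None,
        mode=raw.get("mode", "paper_compat"),
    )
    config = RiskConfig(
        arl=float(raw.get("arl", 1e-5)),
        nd_policy=raw.get("nd_policy", "zero"),
    )
    return scenario, config
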