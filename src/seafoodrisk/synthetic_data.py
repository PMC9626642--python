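"""Synthetic contaminant monitoring surveys with a lognormal hurdle structure.

A monitoring survey measures each analyte in each specimen; a fraction of
measurements falls below the limit of detection (LOD) and is reported only
as ``ND``. The generator emulates that structure with, per analyte:

* a detection (hurdle) probability ``p`` — whether the specimen carries a
  quantifiable residue;
* a lognormal(µ, σ) law for positive concentrations — the standard
  right-skewed model for trace-contaminant data;
* a limit of detection ``lod`` — any value below it is censored to ND
  (internally a sub-LOD value is drawn as lod × U(0,1) but only the ND
  token is ever emitted).

Surveys span labelled seasons with per-season specimen counts (default:
five quarterly collections totalling 86 specimens) and optional
multiplicative seasonal shifts of µ. Everything is reproducible from the
seed. ``summarize_survey`` folds a specimen-level table back into the
frequency / mean ± SD summary shape the analysis pipeline reads, closing
the loop generate → summarize → exposure → risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reference_data import (
    ConcentrationRecord,
    ValidationError,
    ND_TOKEN,
)

__all__ = [
    "AnalyteModel",
    "SurveyConfig",
    "DEFAULT_SEASONS",
    "generate_survey",
    "summarize_survey",
    "records_from_summary",
    "survey_config_from_summary",
    "write_survey_csv",
    "fixture_bundle",
    "FIXTURE_NAMES",
]

#: five quarterly collections, summer 2016 → autumn 2017, totalling 86
DEFAULT_SEASONS: tuple[tuple[str, int], ...] = (
    ("summer_2016", 18),
    ("autumn_2016", 17),
    ("winter_2017", 17),
    ("spring_2017", 17),
    ("autumn_2017", 17),
)


@dataclass(frozen=True)
class AnalyteModel:
    """Hurdle-lognormal generative model for one analyte."""

    analyte_id: str
    detection_p: float
    mu: float
    sigma: float
    lod: float
    units: str = "mg_per_kg"
    basis: str = "wet"

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_p <= 1.0:
            raise ValidationError(
                f"{self.analyte_id}: detection probability {self.detection_p} "
                "outside [0, 1]"
            )
        if self.sigma <= 0:
            raise ValidationError(f"{self.analyte_id}: sigma must be > 0")
        if self.lod <= 0:
            raise ValidationError(f"{self.analyte_id}: lod must be > 0")

    @property
    def detect_mean(self) -> float:
        """Expected positive concentration, exp(µ + σ²/2)."""
        return math.exp(self.mu + self.sigma**2 / 2)


@dataclass(frozen=True)
class SurveyConfig:
    """A full survey: analyte models, season layout, seasonal shifts, seed."""

    analytes: Sequence[AnalyteModel]
    seasons: Sequence[tuple[str, int]] = DEFAULT_SEASONS
    seasonal_multipliers: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.analytes:
            raise ValidationError("survey needs at least one analyte model")
        if any(count <= 0 for _, count in self.seasons):
            raise ValidationError("season specimen counts must be positive")
        if self.seasonal_multipliers is not None:
            labels = {label for label, _ in self.seasons}
            unknown = set(self.seasonal_multipliers) - labels
            if unknown:
                raise ValidationError(f"multipliers for unknown seasons: {unknown}")
            if any(m <= 0 for m in self.seasonal_multipliers.values()):
                raise ValidationError("seasonal multipliers must be positive")

    @property
    def n_specimens(self) -> int:
        return sum(count for _, count in self.seasons)


def generate_survey(config: SurveyConfig) -> pd.DataFrame:
    """Draw a specimen-level concentration table.

    Columns: ``specimen_id, season, analyte_id, value, nd, units, basis``;
    ``value`` is NaN wherever ``nd`` is True (sub-LOD measurements carry no
    number, mirroring how laboratories report them). Identical config and
    seed reproduce the table exactly.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    specimen = 0
    for season, count in config.seasons:
        mult = (
            1.0
            if config.seasonal_multipliers is None
            else config.seasonal_multipliers.get(season, 1.0)
        )
        for _ in range(count):
            specimen += 1
            sid = f"S{specimen:04d}"
            for model in config.analytes:
                detected = rng.random() < model.detection_p
                if detected:
                    value = rng.lognormal(model.mu + math.log(mult), model.sigma)
                    if value < model.lod:
                        # a real draw below the LOD is censored like any ND
                        detected = False
                if not detected:
                    # sub-LOD magnitude drawn but never emitted numerically
                    rng.uniform(0.0, model.lod)
                rows.append(
                    {
                        "specimen_id": sid,
                        "season": season,
                        "analyte_id": model.analyte_id,
                        "value": value if detected else np.nan,
                        "nd": not detected,
                        "units": model.units,
                        "basis": model.basis,
                    }
                )
    return pd.DataFrame(rows)


def write_survey_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a specimen-level table with ND rendered as the literal token."""
    out = table.copy()
    out["value_or_nd"] = [
        ND_TOKEN if nd else repr(float(v))
        for v, nd in zip(out["value"], out["nd"])
    ]
    out = out[["specimen_id", "season", "analyte_id", "value_or_nd", "units", "basis"]]
    out.to_csv(path, index=False)


def summarize_survey(
    table: pd.DataFrame,
    summary: str = "detects",
    nd_policy: str = "zero",
) -> pd.DataFrame:
    """Fold a specimen-level table into a frequency / mean ± SD summary.

    ``summary='detects'`` (default) averages over detected values only —
    the usual way monitoring tables report mean ± SD. ``summary='all'``
    includes NDs at their policy value (0 under ``zero``). Frequencies are
    100 × detected/n. An empty table is an error.
    """
    if len(table) == 0:
        raise ValidationError("cannot summarise an empty survey")
    if summary not in ("detects", "all"):
        raise ValidationError(f"unknown summary kind {summary!r}")
    out_rows = []
    for analyte_id, group in table.groupby("analyte_id", sort=False):
        n = len(group)
        detected = group.loc[~group["nd"], "value"]
        frequency = 100.0 * len(detected) / n
        if summary == "detects":
            if len(detected) == 0:
                mean, sd, nd_flag = 0.0, None, True
            else:
                mean = float(detected.mean())
                sd = float(detected.std(ddof=1)) if len(detected) > 1 else 0.0
                nd_flag = False
        else:
            if nd_policy != "zero":
                raise ValidationError(
                    "all-specimen summary currently supports nd_policy='zero' only"
                )
            values = group["value"].fillna(0.0)
            mean = float(values.mean())
            sd = float(values.std(ddof=1)) if n > 1 else 0.0
            nd_flag = len(detected) == 0
        units = group["units"].iloc[0]
        basis = group["basis"].iloc[0]
        out_rows.append(
            {
                "analyte_id": analyte_id,
                "mean": mean,
                "sd": sd,
                "detection_frequency_pct": frequency,
                "n": n,
                "units": units,
                "basis": basis,
                "nd": nd_flag,
            }
        )
    return pd.DataFrame(out_rows)


def records_from_summary(summary: pd.DataFrame) -> list[ConcentrationRecord]:
    """Convert a summary frame into :class:`ConcentrationRecord` objects."""
    records = []
    for row in summary.itertuples(index=False):
        records.append(
            ConcentrationRecord(
                analyte_id=row.analyte_id,
                mean_concentration=float(row.mean),
                sd=None if row.sd is None or pd.isna(row.sd) else float(row.sd),
                detection_frequency=float(row.detection_frequency_pct),
                n_samples=int(row.n),
                units=row.units,
                basis=row.basis,
                nd_flag=bool(row.nd),
            )
        )
    return records


def survey_config_from_summary(
    records: Sequence[ConcentrationRecord],
    seed: int = 0,
    seasons: Sequence[tuple[str, int]] = DEFAULT_SEASONS,
    default_sigma: float = 0.5,
) -> SurveyConfig:
    """Build a generative model whose summaries resemble a published table.

    Detection probability is the reported frequency; (µ, σ) are the
    lognormal parameters matching the reported mean m and SD s of detects
    (σ² = ln(1 + s²/m²), µ = ln m − σ²/2). Records with no usable SD get
    ``default_sigma``. The LOD is placed at exp(µ − 4σ), deep in the lower
    tail, so censoring of genuine detects is negligible. ND analytes are
    modelled with detection probability 0.
    """
    models = []
    for r in records:
        if r.nd_flag or r.mean_concentration <= 0:
            models.append(
                AnalyteModel(
                    analyte_id=r.analyte_id,
                    detection_p=0.0,
                    mu=0.0,
                    sigma=default_sigma,
                    lod=1e-6,
                    units=r.units,
                    basis=r.basis,
                )
            )
            continue
        m = r.mean_concentration
        if r.sd is not None and r.sd > 0:
            sigma2 = math.log(1.0 + (r.sd / m) ** 2)
            sigma = math.sqrt(sigma2)
        else:
            sigma = default_sigma
            sigma2 = sigma**2
        mu = math.log(m) - sigma2 / 2.0
        models.append(
            AnalyteModel(
                analyte_id=r.analyte_id,
                detection_p=r.detection_frequency / 100.0,
                mu=mu,
                sigma=sigma,
                lod=math.exp(mu - 4.0 * sigma),
                units=r.units,
                basis=r.basis,
            )
        )
    return SurveyConfig(analytes=models, seasons=seasons, seed=seed)


# ---------------------------------------------------------------------------
# Bundled fixtures: the published summary tables as ready-to-run inputs

FIXTURE_NAMES = (
    "table1_tm.csv",
    "table1_ocp.csv",
    "table4_ocp.csv",
    "table4_toxrefs.csv",
    "metal_toxrefs.csv",
    "scenario_default.yaml",
)


def fixture_bundle(dest: str | Path | None = None) -> dict[str, Path]:
    """Paths to the bundled summary-table fixtures (optionally copied to dest).

    The bundle carries the survey's published per-analyte summaries (metal
    and OCP concentration tables), the OCP concentrations on the mg/kg
    scale used for dose arithmetic, the toxicity-reference tables and a
    default scenario config — enough to run every pipeline stage with no
    network access.
    """
    from importlib import resources

    root = resources.files("seafoodrisk") / "_fixtures"
    out: dict[str, Path] = {}
    for name in FIXTURE_NAMES:
        src = root / name
        if dest is None:
            out[name] = Path(str(src))
        else:
            dest_dir = Path(dest)
            dest_dir.mkdir(parents=True, exist_ok=True)
            target = dest_dir / name
            target.write_text(src.read_text(encoding="utf-8"), encoding="utf-8")
            out[name] = target
    return out
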