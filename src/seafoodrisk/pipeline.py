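"""End-to-end pipeline: read tables → exposure → risk → diagnostics → report.

The pipeline is a pure function of its input files and configuration:
identical inputs produce byte-identical outputs, rows ordered by
contaminant class then analyte id. Outputs are plain CSV/JSON plus a run
log; every quantity that could not be computed (missing RfD or CSF) is
logged explicitly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .exposure import _UNIT_TOKENS
from .reference_data import (
    ConcentrationRecord,
    ExposureScenario,
    Registry,
    RiskConfig,
    ValidationError,
    analytes_from_table,
    build_registry,
    convert_units,
    read_concentration_table,
    read_scenario,
    read_toxicity_table,
)
from .risk import NOT_COMPUTABLE, compute_risk
from .source_diagnostics import (
    TECHNICAL_MIXTURES,
    classify_source,
    compare_to_technical,
    family_composition,
)

__all__ = ["ReportBundle", "run_pipeline", "scenario_sweep", "render_tables"]

logger = logging.getLogger("seafoodrisk.pipeline")

OUTPUT_FILES = (
    "exposure.csv",
    "risk.csv",
    "aggregate.json",
    "profiles.json",
    "sweep.csv",
    "run.log",
)

_DIAGNOSED_FAMILIES = ("DDx", "drin", "HCH", "chlordane", "endosulfan")


@dataclass
class ReportBundle:
    """All pipeline products plus metadata sufficient for exact re-runs."""

    exposure: pd.DataFrame
    risk: pd.DataFrame
    aggregate: dict
    profiles: dict
    sweep: pd.DataFrame
    metadata: dict


def _as_paths(paths) -> list[Path]:
    if isinstance(paths, (str, Path)):
        return [Path(paths)]
    return [Path(p) for p in paths]


def _opt(value):
    """Marker/None → None for serialisation; numbers pass through."""
    if value is NOT_COMPUTABLE or value is None:
        return None
    if isinstance(value, float) and math.isinf(value):
        return math.inf
    return value


def _config_hash(files: Sequence[Path], scenario: ExposureScenario,
                 config: RiskConfig, rates: Sequence[float]) -> str:
    h = hashlib.sha256()
    for p in files:
        h.update(p.read_bytes())
    h.update(repr(scenario).encode())
    h.update(repr(config).encode())
    h.update(repr(list(rates)).encode())
    return h.hexdigest()


def scenario_sweep(
    records: Sequence[ConcentrationRecord],
    registry: Registry,
    scenario: ExposureScenario,
    config: RiskConfig,
    rates: Sequence[float],
) -> pd.DataFrame:
    """Risk indices per analyte over a grid of consumption rates (g/day).

    All indices are linear in the intake rate, so each block must equal the
    base block scaled by rate/base_rate; that identity is re-verified
    internally (to 1e-12 relative) as a guard against regressions.
    ``rate=0`` rows are computed at the limit (all indices zero).
    """
    if len(rates) == 0:
        raise ValidationError("scenario sweep needs at least one rate")
    if any(r < 0 for r in rates):
        raise ValidationError("consumption rates must be >= 0")
    base_results, _ = compute_risk(records, registry, scenario, config)
    blocks = []
    for rate in rates:
        if rate == 0:
            results = [
                r.__class__(**{**r.__dict__, "edi": 0.0,
                               "thq": 0.0 if r.thq is not NOT_COMPUTABLE else r.thq,
                               "hq": 0.0 if r.hq is not NOT_COMPUTABLE else r.hq,
                               "ilcr": 0.0 if r.ilcr is not NOT_COMPUTABLE else r.ilcr})
                for r in base_results
            ]
        else:
            sc = ExposureScenario(
                vir_d=rate, bw=scenario.bw, ed=scenario.ed, ef=scenario.ef,
                at=scenario.at, mode=scenario.mode,
            )
            results, _ = compute_risk(records, registry, sc, config)
            scale = rate / scenario.vir_d
            for base, res in zip(base_results, results):
                for attr in ("edi", "thq", "hq", "ilcr"):
                    b, v = getattr(base, attr), getattr(res, attr)
                    if b is NOT_COMPUTABLE or v is NOT_COMPUTABLE:
                        continue
                    if not math.isclose(v, b * scale, rel_tol=1e-12, abs_tol=1e-300):
                        raise AssertionError(
                            f"sweep linearity violated for {res.analyte_id}.{attr}"
                        )
        for res in results:
            blocks.append(
                {
                    "rate_g_per_day": rate,
                    "analyte_id": res.analyte_id,
                    "class": res.contaminant_class,
                    "edi": res.edi,
                    "thq": _opt(res.thq),
                    "hq": _opt(res.hq),
                    "ilcr": _opt(res.ilcr),
                }
            )
    return pd.DataFrame(blocks)


def _build_profiles(records, registry, config) -> dict:
    """Composition, classification and technical divergence per OCP family."""
    profiles: dict = {}
    present = {r.analyte_id for r in records}
    for family in _DIAGNOSED_FAMILIES:
        member_ids = {a.id for a in registry.family_members(family)}
        if not member_ids & present:
            continue
        profile = family_composition(records, family, registry, config.nd_policy)
        profile = classify_source(profile)
        entry = {
            "fractions": {k: v for k, v in sorted(profile.fractions.items())},
            "total_concentration": profile.total_concentration,
            "classification": profile.classification,
            "rule_fired": profile.rule_fired,
        }
        if family in TECHNICAL_MIXTURES and profile.total_concentration > 0:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                entry["technical_divergence"] = compare_to_technical(profile)
        profiles[family] = entry
    return profiles


def run_pipeline(
    concentrations,
    toxicity,
    scenario_path=None,
    out_dir: str | Path | None = None,
    rates: Sequence[float] = (32.88, 120.0),
    scenario: ExposureScenario | None = None,
    config: RiskConfig | None = None,
) -> ReportBundle:
    """Run every stage on CSV/YAML inputs and (optionally) write the report.

    ``concentrations`` and ``toxicity`` are paths (or lists of paths, e.g.
    the metal and OCP tables separately). The scenario comes either from a
    YAML path or from explicit objects. When ``out_dir`` is given the
    report files are written there; on any error partial outputs are
    removed and the error re-raised.
    """
    conc_paths = _as_paths(concentrations)
    tox_paths = _as_paths(toxicity)
    if scenario_path is not None:
        scenario_read, config_read = read_scenario(scenario_path)
        scenario = scenario or scenario_read
        config = config or config_read
    scenario = scenario or ExposureScenario()
    config = config or RiskConfig()

    records: list[ConcentrationRecord] = []
    analytes = []
    seen = set()
    for p in conc_paths:
        records.extend(read_concentration_table(p, nd_policy=config.nd_policy))
        for a in analytes_from_table(p):
            if a.id not in seen:
                seen.add(a.id)
                analytes.append(a)
    refs = []
    for p in tox_paths:
        refs.extend(read_toxicity_table(p))
    registry = build_registry(analytes, refs)

    # stable output ordering: class then id
    order = {a.id: (a.contaminant_class, a.id) for a in analytes}
    records.sort(key=lambda r: order[r.analyte_id])

    normalized = [convert_units(r, "mg_per_kg") for r in records]

    if records:
        results, aggregate = compute_risk(
            normalized, registry, scenario, config, screening_records=records
        )
        sweep = scenario_sweep(normalized, registry, scenario, config, rates)
        profiles = _build_profiles(records, registry, config)
    else:
        logger.warning("empty concentration table: producing empty report")
        results, aggregate = [], None
        sweep = pd.DataFrame(
            columns=["rate_g_per_day", "analyte_id", "class", "edi", "thq", "hq", "ilcr"]
        )
        profiles = {}

    exposure_df = pd.DataFrame(
        [
            {
                "analyte_id": r.analyte_id,
                "class": r.contaminant_class,
                "edi": r.edi,
                "units": _UNIT_TOKENS[scenario.mode],
                "mode": scenario.mode,
            }
            for r in results
        ],
        columns=["analyte_id", "class", "edi", "units", "mode"],
    )
    risk_df = pd.DataFrame(
        [
            {
                "analyte_id": r.analyte_id,
                "class": r.contaminant_class,
                "edi": r.edi,
                "thq": _opt(r.thq),
                "hq": _opt(r.hq),
                "ilcr": _opt(r.ilcr),
                "cr_lim_kg_day": _opt(r.cr_lim_kg_day),
                "exceeds_mrl": r.exceeds_mrl,
                "fold_mrl": r.fold_mrl,
                "flags": ";".join(r.flags),
            }
            for r in results
        ],
        columns=[
            "analyte_id", "class", "edi", "thq", "hq", "ilcr",
            "cr_lim_kg_day", "exceeds_mrl", "fold_mrl", "flags",
        ],
    )
    aggregate_block = {
        "hi": None
        if aggregate is None
        else {
            "value": aggregate.hi.value,
            "partial": aggregate.hi.partial,
            "skipped": list(aggregate.hi.skipped),
            "contributors": dict(aggregate.hi.contributors),
        },
        "thq_total": None
        if aggregate is None
        else {
            "value": aggregate.thq_total.value,
            "partial": aggregate.thq_total.partial,
            "skipped": list(aggregate.thq_total.skipped),
            "contributors": dict(aggregate.thq_total.contributors),
        },
        "scenario": {
            "vir_d_g_per_day": scenario.vir_d,
            "bw_kg": scenario.bw,
            "ed_years": scenario.ed,
            "ef_days_per_year": scenario.ef,
            "at_days": scenario.at,
            "mode": scenario.mode,
        },
        "thresholds": {
            "thq_tm": config.thq_threshold_tm,
            "hq_ocp": config.hq_threshold_ocp,
            "ilcr": config.ilcr_threshold,
            "arl": config.arl,
        },
    }
    metadata = {
        "version": __version__,
        "config_hash": _config_hash(conc_paths + tox_paths, scenario, config, rates),
        "n_analytes": len(results),
        "rates_g_per_day": list(rates),
        "nd_policy": config.nd_policy,
    }
    bundle = ReportBundle(
        exposure=exposure_df,
        risk=risk_df,
        aggregate=aggregate_block,
        profiles=profiles,
        sweep=sweep,
        metadata=metadata,
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir), results)
    return bundle


def _write_bundle(bundle: ReportBundle, out_dir: Path, results) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        p = out_dir / "exposure.csv"
        bundle.exposure.to_csv(p, index=False)
        written.append(p)
        p = out_dir / "risk.csv"
        bundle.risk.to_csv(p, index=False)
        written.append(p)
        p = out_dir / "aggregate.json"
        p.write_text(json.dumps(bundle.aggregate, indent=2, sort_keys=True),
                     encoding="utf-8")
        written.append(p)
        p = out_dir / "profiles.json"
        p.write_text(json.dumps(bundle.profiles, indent=2, sort_keys=True),
                     encoding="utf-8")
        written.append(p)
        p = out_dir / "sweep.csv"
        bundle.sweep.to_csv(p, index=False)
        written.append(p)
        log_path = out_dir / "run.log"
        lines = [
            f"{datetime.now(timezone.utc).isoformat()} INFO pipeline "
            f"version={bundle.metadata['version']} "
            f"config_hash={bundle.metadata['config_hash']}"
        ]
        for r in results:
            for note in r.notes:
                lines.append(
                    f"{datetime.now(timezone.utc).isoformat()} WARNING "
                    f"{r.analyte_id}: {note}"
                )
        if not results:
            lines.append(
                f"{datetime.now(timezone.utc).isoformat()} WARNING "
                "empty concentration table"
            )
        log_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(log_path)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def render_tables(
    bundle: ReportBundle, precision: dict[str, int] | None = None
) -> dict[str, pd.DataFrame]:
    """Report tables rounded (half-even) per column, raw values preserved.

    Every rounded numeric column keeps its unrounded twin in a parallel
    ``<name>_raw`` column, so the formatted tables always parse back to the
    computed values.
    """
    precision = precision or dict(RiskConfig().report_precision)
    out: dict[str, pd.DataFrame] = {}
    for name, df in (("exposure", bundle.exposure), ("risk", bundle.risk),
                     ("sweep", bundle.sweep)):
        df = df.copy()
        for col, nd in precision.items():
            if col in df.columns:
                df[f"{col}_raw"] = df[col]
                df[col] = df[col].map(
                    lambda v, nd=nd: v if v is None or (isinstance(v, float) and not np.isfinite(v)) else round(v, nd)
                )
        out[name] = df
    return out
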