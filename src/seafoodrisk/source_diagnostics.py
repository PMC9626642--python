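"""Isomer/metabolite composition of OCP families and source-age classification.

Weathering changes the composition of a pesticide family in a predictable
direction: parent compounds (p,p'-DDT, aldrin, heptachlor, endosulfan I/II)
degrade into longer-lived metabolites (DDE/DDD, dieldrin, heptachlor
epoxide, endosulfan sulfate), and technical mixtures (e.g. HCH with
60–70 % α, endosulfan at 70:30 I:II) drift away from their manufactured
fingerprint. Comparing the observed within-family fractions to those
fingerprints therefore separates *historical* residues from *recent*
applications.

The classifier here is a small declarative rule table — one rule per
family, all thresholds user-editable — and every classification reports
the exact rule it fired, so the reasoning is auditable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .reference_data import (
    ConcentrationRecord,
    Registry,
    ValidationError,
    build_registry,
    DEFAULT_ANALYTES,
)

__all__ = [
    "CompositionProfile",
    "ClassificationRules",
    "DEFAULT_RULES",
    "TECHNICAL_MIXTURES",
    "family_composition",
    "classify_source",
    "compare_to_technical",
]

#: Manufactured (technical-product) compositions used as fingerprints.
#: Endosulfan is the nominal 70:30 I:II product. The HCH entry holds the
#: midpoints of the published technical ranges (α 60–70 %, β 5–12 %,
#: γ 10–15 %, δ 6–10 %); the midpoints sum to 0.94, not 1, and are used
#: as-is (unnormalised) in divergence computations.
TECHNICAL_MIXTURES: dict[str, dict[str, float]] = {
    "endosulfan": {"endosulfan_i": 0.70, "endosulfan_ii": 0.30},
    "HCH": {
        "alpha_hch": 0.65,
        "beta_hch": 0.085,
        "gamma_hch": 0.125,
        "delta_hch": 0.08,
    },
}


@dataclass(frozen=True)
class CompositionProfile:
    """Within-family mass fractions and (optionally) a source classification."""

    family: str
    fractions: Mapping[str, float]
    total_concentration: float
    classification: str = "unclassified"
    rule_fired: str = ""

    def __post_init__(self) -> None:
        if self.total_concentration > 0:
            total = math.fsum(self.fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"{self.family}: fractions sum to {total}, not 1"
                )

    def fraction(self, member: str) -> float:
        return self.fractions.get(member, 0.0)


@dataclass(frozen=True)
class ClassificationRules:
    """Thresholds of the per-family source-age rules (all configurable).

    * ``ddx_parent_max`` — DDx is *historical* when the parent DDT fraction
      is below this and the DDE+DDD metabolites dominate;
    * ``drin_margin`` — drins are *historical* when dieldrin+endrin exceed
      aldrin (aldrin oxidises to dieldrin) by at least this margin;
    * ``hch_gamma_historical_max`` / ``hch_gamma_lindane_min`` — a γ-HCH
      fraction below the first bound, with every isomer present, indicates
      aged technical HCH/lindane; above the second it resembles fresh
      lindane (99 % γ);
    * ``chlordane_parent_ratio_max`` — chlordane is *historical* when the
      heptachlor + heptachlor-epoxide share is at most this multiple of the
      γ-chlordane share;
    * ``endosulfan_tolerance`` — absolute tolerance on the parent
      endosulfan-I fraction around the 70:30 technical split for calling
      the input *recent* when the sulfate metabolite is also present.
    """

    ddx_parent_max: float = 0.10
    drin_margin: float = 0.0
    hch_gamma_historical_max: float = 0.50
    hch_gamma_lindane_min: float = 0.90
    chlordane_parent_ratio_max: float = 0.10
    endosulfan_tolerance: float = 0.20
    endosulfan_technical_i: float = 0.70


DEFAULT_RULES = ClassificationRules()


def family_composition(
    records: Sequence[ConcentrationRecord],
    family: str,
    registry: Registry | None = None,
    nd_policy: str = "zero",
) -> CompositionProfile:
    """Fractions of each family member in the family's summed mean concentration.

    Members flagged ND contribute the value their record carries under the
    chosen nd-policy (0 under ``zero``). All member records must share
    units and basis. An empty membership is an error; a family whose total
    is zero yields all-zero fractions and is classifiable only as
    *indeterminate*.
    """
    registry = registry or build_registry(DEFAULT_ANALYTES)
    member_ids = {a.id for a in registry.family_members(family)}
    if not member_ids:
        raise ValidationError(f"no analytes registered for family {family!r}")
    members = [r for r in records if r.analyte_id in member_ids]
    if not members:
        raise ValidationError(f"no records found for family {family!r}")
    units = {(r.units, r.basis) for r in members}
    if len(units) > 1:
        raise ValidationError(
            f"family {family!r}: mixed units/basis {sorted(units)} — convert first"
        )
    values = {r.analyte_id: (0.0 if r.nd_flag and nd_policy == "zero" else r.mean_concentration) for r in members}
    total = math.fsum(values.values())
    if total == 0:
        fractions = {k: 0.0 for k in values}
    else:
        fractions = {k: v / total for k, v in values.items()}
    return CompositionProfile(
        family=family, fractions=fractions, total_concentration=total
    )


# ---------------------------------------------------------------------------
# Classification rules (one function per family)

def _classify_ddx(p: CompositionProfile, r: ClassificationRules):
    parent = p.fraction("ddt")
    metabolites = p.fraction("dde") + p.fraction("ddd")
    if parent < r.ddx_parent_max and metabolites > 0.5:
        return (
            "historical",
            f"DDT fraction {parent:.3f} < {r.ddx_parent_max:g} with DDE+DDD "
            f"dominant ({metabolites:.2f}): weathered residue, no recent DDT input",
        )
    if parent > 0.5:
        return (
            "recent",
            f"parent DDT dominates ({parent:.2f}): fresh application likely",
        )
    return ("mixed", f"DDT fraction {parent:.2f}: neither aged nor fresh signature")


def _classify_drin(p: CompositionProfile, r: ClassificationRules):
    aldrin = p.fraction("aldrin")
    metabolites = p.fraction("dieldrin") + p.fraction("endrin")
    if metabolites > aldrin + r.drin_margin:
        return (
            "historical",
            f"dieldrin+endrin ({metabolites:.2f}) exceed aldrin ({aldrin:.2f}): "
            "aldrin has oxidised to dieldrin, historical input",
        )
    if aldrin > metabolites:
        return (
            "recent",
            f"aldrin ({aldrin:.2f}) exceeds its oxidation products "
            f"({metabolites:.2f}): recent input",
        )
    return ("mixed", "aldrin and its oxidation products balanced")


def _classify_hch(p: CompositionProfile, r: ClassificationRules):
    gamma = p.fraction("gamma_hch")
    all_present = all(
        p.fraction(m) > 0
        for m in ("alpha_hch", "beta_hch", "gamma_hch", "delta_hch")
    )
    if gamma >= r.hch_gamma_lindane_min:
        return (
            "recent",
            f"gamma-HCH fraction {gamma:.2f} matches fresh lindane (99% gamma)",
        )
    if all_present and gamma < r.hch_gamma_historical_max:
        return (
            "historical",
            f"all isomers present with gamma fraction {gamma:.3f} < "
            f"{r.hch_gamma_historical_max:g}: aged technical HCH / lindane use",
        )
    return ("mixed", f"gamma fraction {gamma:.2f} without a full isomer suite")


def _classify_chlordane(p: CompositionProfile, r: ClassificationRules):
    gamma = p.fraction("gamma_chlordane")
    parents = p.fraction("heptachlor") + p.fraction("heptachlor_epoxide")
    if gamma > 0 and parents <= r.chlordane_parent_ratio_max * gamma:
        return (
            "historical",
            f"heptachlor+epoxide share ({parents:.4f}) is <= "
            f"{r.chlordane_parent_ratio_max:g}x the gamma-chlordane share "
            f"({gamma:.3f}): aged technical chlordane",
        )
    return ("mixed", "heptachlor components not negligible against gamma-chlordane")


def _classify_endosulfan(p: CompositionProfile, r: ClassificationRules):
    sulfate = p.fraction("endosulfan_sulfate")
    i, ii = p.fraction("endosulfan_i"), p.fraction("endosulfan_ii")
    parent_total = i + ii
    if sulfate > 0 and parent_total > 0:
        i_share = i / parent_total
        dev = abs(i_share - r.endosulfan_technical_i)
        if dev <= r.endosulfan_tolerance:
            return (
                "recent",
                f"sulfate metabolite present with parent I:II split "
                f"{i_share:.2f}:{1 - i_share:.2f} within {r.endosulfan_tolerance:g} "
                f"of the 70:30 technical product: recent use",
            )
        return (
            "mixed",
            f"sulfate present but parent split {i_share:.2f} deviates "
            f"{dev:.2f} from technical 70:30",
        )
    if sulfate > 0:
        return (
            "historical",
            "only the sulfate degradation product remains: historical input",
        )
    return ("mixed", "no sulfate metabolite detected")


_RULE_DISPATCH = {
    "DDx": _classify_ddx,
    "drin": _classify_drin,
    "HCH": _classify_hch,
    "chlordane": _classify_chlordane,
    "endosulfan": _classify_endosulfan,
}


def classify_source(
    profile: CompositionProfile,
    rules: ClassificationRules = DEFAULT_RULES,
) -> CompositionProfile:
    """Apply the family's rule and return the profile with its classification.

    Pure function of (profile, rules); an all-zero profile is
    *indeterminate*; an unknown family is an error.
    """
    if profile.total_concentration == 0:
        return replace(
            profile,
            classification="indeterminate",
            rule_fired="family total concentration is zero",
        )
    try:
        rule = _RULE_DISPATCH[profile.family]
    except KeyError:
        raise ValidationError(
            f"no classification rule for family {profile.family!r}"
        ) from None
    classification, fired = rule(profile, rules)
    return replace(profile, classification=classification, rule_fired=fired)


def compare_to_technical(
    profile: CompositionProfile,
    technical_profile: Mapping[str, float] | None = None,
) -> float:
    """Total variation distance ½ Σ |f_i − t_i| to the technical fingerprint.

    Computed over the common member set; when the member sets differ a
    warning is emitted and the extra members are ignored. The distance is
    symmetric in its arguments and lies in [0, 1].
    """
    if technical_profile is None:
        technical_profile = TECHNICAL_MIXTURES.get(profile.family)
        if technical_profile is None:
            raise ValidationError(
                f"no technical mixture known for family {profile.family!r}"
            )
    observed = dict(profile.fractions)
    if set(observed) != set(technical_profile):
        warnings.warn(
            f"{profile.family}: member sets differ between profile and technical "
            "mixture; distance computed on their intersection",
            stacklevel=2,
        )
    members = set(observed) & set(technical_profile)
    return 0.5 * math.fsum(
        abs(observed[m] - technical_profile[m]) for m in members
    )
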