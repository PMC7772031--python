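"""CatLet score engine.

Per-lesion score = vessel weight (mass units, derived under the conservation
laws) x multiplication factor (5.0 for any total occlusion, 2.0 for a 50-99%
stenosis), optionally reduced by the adapted modification: side branches
arising proximal to the lesion are subtracted at the lesion's own factor,
floored at zero.  The eight adverse angiographic characteristics are recorded
qualitatively only and never contribute points; diffuse disease / small
vessels is additionally excluded from every quantitative path.  Totals are
binned into risk tiers at the tertile cut-offs <=9 / 10-14 / >15.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

from .coronary_model import (
    ContractError,
    CoronaryTree,
    Lesion,
    OcclusionClass,
    lesion_eligibility,
)
from .pattern_weights import format_weight

__all__ = [
    "OCCLUSION_FACTOR",
    "NONOCCLUSION_FACTOR",
    "LESION_TYPES",
    "lesion_type",
    "CatLetLesionScore",
    "ScoreReport",
    "catlet_lesion_score",
    "apply_modification",
    "catlet_total",
    "catlet_risk_tier",
]

#: Multiplication factors, shared with the SYNTAX score.
OCCLUSION_FACTOR = Fraction(5)
NONOCCLUSION_FACTOR = Fraction(2)

#: The six-type lesion taxonomy (native/in-stent x nonocclusion/ATO/CTO).
LESION_TYPES = (
    "native nonocclusion",
    "native ATO",
    "native CTO",
    "in-stent nonocclusion",
    "in-stent ATO",
    "in-stent CTO",
)


def lesion_type(lesion: Lesion) -> str:
    """Classify a lesion into the six-type taxonomy."""
    prefix = "in-stent" if lesion.in_stent else "native"
    if lesion.occlusion is OcclusionClass.ACUTE_TOTAL:
        kind = "ATO"
    elif lesion.occlusion is OcclusionClass.CHRONIC_TOTAL:
        kind = "CTO"
    else:
        kind = "nonocclusion"
    return f"{prefix} {kind}"


@dataclass(frozen=True)
class CatLetLesionScore:
    """One lesion's score: value = weight x factor − modification subtrahend (>= 0)."""

    lesion: Lesion
    weight: Fraction
    factor: Fraction
    lesion_type: str
    subtrahend: Fraction = Fraction(0)
    warnings: tuple = ()

    @property
    def raw(self) -> Fraction:
        return self.weight * self.factor

    @property
    def value(self) -> Fraction:
        return max(Fraction(0), self.raw - self.subtrahend)

    def __str__(self) -> str:
        return (f"{self.lesion_type} @ {self.lesion.node_id}: "
                f"{format_weight(self.weight)} x {self.factor} "
                f"- {format_weight(self.subtrahend)} = {format_weight(self.value)}")


@dataclass
class ScoreReport:
    """Full CatLet report: per-lesion scores, total, tier, qualitative record.

    ``qualitative`` carries the eight adverse-characteristic booleans for
    EVERY lesion on the tree (eligible or not), verbatim and without any
    numeric contribution.  ``culprit_nodes`` indicates culprit vessels;
    this is annotation only and never alters scoring.
    """

    lesion_scores: list = field(default_factory=list)
    total: Fraction = Fraction(0)
    tier: str = "low"
    tier_note: Optional[str] = None
    qualitative: list = field(default_factory=list)  # (node_id, flags dict)
    culprit_nodes: list = field(default_factory=list)
    excluded: list = field(default_factory=list)     # (lesion, reason)
    warnings: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "lesions": [
                {
                    "node": s.lesion.node_id,
                    "type": s.lesion_type,
                    "weight": float(s.weight),
                    "factor": float(s.factor),
                    "subtrahend": float(s.subtrahend),
                    "value": float(s.value),
                    "warnings": list(s.warnings),
                }
                for s in self.lesion_scores
            ],
            "total": float(self.total),
            "tier": self.tier,
            "tier_note": self.tier_note,
            "qualitative_record": [
                {"node": node, "flags": flags} for node, flags in self.qualitative
            ],
            "culprit_nodes": list(self.culprit_nodes),
            "excluded": [
                {"node": lesion.node_id, "reason": reason}
                for lesion, reason in self.excluded
            ],
            "warnings": list(self.warnings),
        }


def _factor_for(lesion: Lesion) -> Fraction:
    return OCCLUSION_FACTOR if lesion.is_occlusion else NONOCCLUSION_FACTOR


def catlet_lesion_score(lesion: Lesion, weights: Mapping[str, Fraction]) -> CatLetLesionScore:
    """Score one eligible lesion: weight x 5.0 (occlusion) or x 2.0 (50-99%).

    The caller must have filtered for eligibility; an ineligible lesion or a
    lesion whose node has no derived weight is a contract error.
    """
    check = lesion_eligibility(lesion, lesion.reference_diameter_mm)
    if not check:
        raise ContractError(
            f"lesion on {lesion.node_id!r} is ineligible ({check.reason}); "
            "filter before scoring"
        )
    if lesion.node_id not in weights:
        raise ContractError(f"no derived weight for node {lesion.node_id!r}")
    return CatLetLesionScore(
        lesion=lesion,
        weight=Fraction(weights[lesion.node_id]),
        factor=_factor_for(lesion),
        lesion_type=lesion_type(lesion),
    )


def apply_modification(
    score: CatLetLesionScore,
    preceding_branches: Sequence,
) -> CatLetLesionScore:
    """Adapted modification: subtract each preceding side branch's weight,
    scaled by the lesion's own multiplication factor.

    ``preceding_branches`` are the side branches arising proximal to the
    lesion on the same vessel (their diseased or normal status is
    irrelevant); each entry is a Fraction weight or an object with a
    ``weight`` attribute.  An empty list is the identity.  If the subtrahend
    exceeds weight x factor the value is clamped to 0 and a warning recorded.
    """
    branch_weights = [
        Fraction(getattr(b, "weight", b)) for b in preceding_branches
    ]
    if not branch_weights:
        return score
    subtrahend = sum(branch_weights, Fraction(0)) * score.factor
    warnings = score.warnings
    if subtrahend > score.raw:
        warnings = warnings + (
            f"modification subtrahend {format_weight(subtrahend)} exceeds "
            f"{format_weight(score.raw)}; value clamped to 0",
        )
    return replace(score, subtrahend=score.subtrahend + subtrahend,
                   warnings=warnings)


def catlet_total(
    tree: CoronaryTree,
    weights: Mapping[str, Fraction],
    *,
    modification: bool = True,
) -> ScoreReport:
    """Score a whole tree: filter eligible lesions, score, modify, sum, bin.

    Adverse-characteristic flags are recorded verbatim for every lesion —
    scored or not — and contribute nothing numerically.
    """
    report = ScoreReport()
    for lesion in tree.lesions:
        report.qualitative.append((lesion.node_id, lesion.flags.as_dict()))
        if lesion.culprit:
            report.culprit_nodes.append(lesion.node_id)
        check = lesion_eligibility(lesion, lesion.reference_diameter_mm)
        if not check:
            report.excluded.append((lesion, check.reason))
            continue
        score = catlet_lesion_score(lesion, weights)
        if modification and lesion.preceding_branch_ids:
            branches = []
            for branch_id in lesion.preceding_branch_ids:
                if branch_id not in weights:
                    raise ContractError(
                        f"no derived weight for preceding branch {branch_id!r}"
                    )
                branches.append(weights[branch_id])
            score = apply_modification(score, branches)
        report.lesion_scores.append(score)
        report.warnings.extend(score.warnings)
    report.total = sum((s.value for s in report.lesion_scores), Fraction(0))
    report.tier = catlet_risk_tier(report.total)
    if Fraction(14) < report.total <= Fraction(15):
        report.tier_note = (
            "total falls in the (14, 15] gap between the printed tertile "
            "bands 10-14 and >15; binned as intermediate"
        )
    return report


def catlet_risk_tier(score) -> str:
    """Tertile risk tier: low <=9, intermediate (9, 15], high >15.

    The printed bands (<=9, 10-14, >15) leave (14, 15] unassigned; scores in
    the gap are binned intermediate and flagged via ScoreReport.tier_note.
    """
    if score < 0:
        raise ValueError(f"score must be non-negative, got {score}")
    if score <= 9:
        return "low"
    if score > 15:
        return "high"
    return "intermediate"
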