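"""Anatomical SYNTAX lesion scoring, for comparison against CatLet.

The SYNTAX score assigns each coronary segment a fixed, nomenclature-based
weighting factor that depends only on dominance (right/left), multiplies it
by 5.0 for a total occlusion or 2.0 for a 50-99% stenosis, and adds directly
assigned points for adverse lesion characteristics.  This engine reproduces
that arithmetic with the two components always reported separately, supports
the adapted side-branch modification, and ships a conservation audit that
makes the weighting scheme's violation of the law of flow conservation
computable: along the RCA the parent segments are weighted 1.0 while their
daughters (PDA 1.0 plus 0.5-weighted posterolateral branches) sum well above
that.

Shipped right-dominance weights: the RCA-system rows are the published
SYNTAX values (segments 1-4 at 1.0; 16/16a/16b/16c at 0.5); the remaining
segments are completed from the published SYNTAX/Leaman convention.  Every
entry carries a provenance tag (``rca_table`` / ``standard`` / ``user``) so
a table can be audited or overridden via CSV.  Left-dominance rows are
config-only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping, Optional, Sequence

from .coronary_model import (
    ADVERSE_CHARACTERISTICS,
    ConfigurationError,
    ContractError,
    CoronaryTree,
    Lesion,
    lesion_eligibility,
)
from .catlet_engine import (
    NONOCCLUSION_FACTOR,
    OCCLUSION_FACTOR,
    lesion_type,
)
from .pattern_weights import format_weight

__all__ = [
    "WeightEntry",
    "SyntaxWeightTable",
    "DEFAULT_ADVERSE_POINTS",
    "SyntaxLesionScore",
    "SyntaxReport",
    "ConservationFinding",
    "syntax_segment_weight",
    "syntax_lesion_score",
    "syntax_adapted_modification",
    "syntax_total",
    "syntax_tertile",
    "flow_conservation_audit",
    "syntax_weight_map",
]


@dataclass(frozen=True)
class WeightEntry:
    segment: str
    dominance: str
    weight: Fraction
    provenance: str
    name: str = ""

    def __post_init__(self):
        if self.weight <= 0:
            raise ConfigurationError(
                f"SYNTAX weight for segment {self.segment!r} must be > 0"
            )


# Right-dominance RCA-system rows of the published SYNTAX weighting.
_RCA_RIGHT_ROWS = (
    ("1", "RCA proximal", "1"),
    ("2", "RCA mid", "1"),
    ("3", "RCA distal", "1"),
    ("4", "Posterior descending artery", "1"),
    ("16", "Posterolateral branch from the RCA", "1/2"),
    ("16a", "Posterolateral branch from the RCA", "1/2"),
    ("16b", "Posterolateral branch from the RCA", "1/2"),
    ("16c", "Posterolateral branch from the RCA", "1/2"),
)

# Remaining right-dominance segments, completed from the published
# SYNTAX/Leaman convention (the left system is dominance-invariant here).
_STANDARD_RIGHT_ROWS = (
    ("5", "Left main", "5"),
    ("6", "LAD proximal", "7/2"),
    ("7", "LAD mid", "5/2"),
    ("8", "LAD apical", "1"),
    ("9", "First diagonal", "1"),
    ("9a", "Add. first diagonal", "1"),
    ("10", "Second diagonal", "1/2"),
    ("10a", "Add. second diagonal", "1/2"),
    ("11", "LCX proximal", "3/2"),
    ("12", "Intermediate/anterolateral", "1"),
    ("12a", "Obtuse marginal a", "1"),
    ("12b", "Obtuse marginal b", "1"),
    ("13", "LCX distal", "1/2"),
    ("14", "Left posterolateral", "1/2"),
    ("14a", "Left posterolateral a", "1/2"),
    ("14b", "Left posterolateral b", "1/2"),
)


class SyntaxWeightTable:
    """Mapping (segment, dominance) -> weighting factor, with provenance.

    The shipped default covers right dominance only; left-dominance rows (and
    any overrides) are loaded from a user CSV with columns
    ``segment,dominance,weight[,provenance][,name]``.
    """

    def __init__(self, entries: Sequence[WeightEntry]):
        self._entries: dict = {}
        for entry in entries:
            self._entries[(entry.segment, entry.dominance)] = entry

    @classmethod
    def default(cls) -> "SyntaxWeightTable":
        entries = [
            WeightEntry(seg, "right", Fraction(w), "rca_table", name)
            for seg, name, w in _RCA_RIGHT_ROWS
        ] + [
            WeightEntry(seg, "right", Fraction(w), "standard", name)
            for seg, name, w in _STANDARD_RIGHT_ROWS
        ]
        return cls(entries)

    @classmethod
    def from_csv(cls, path, *, base: Optional["SyntaxWeightTable"] = None
                 ) -> "SyntaxWeightTable":
        """Load/override entries from CSV, layered over ``base`` if given."""
        entries = list(base._entries.values()) if base is not None else []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            fields = reader.fieldnames or []
            for column in ("segment", "dominance", "weight"):
                if column not in fields:
                    raise ConfigurationError(
                        f"weight table {path} missing column {column!r}"
                    )
            for row in reader:
                entries.append(WeightEntry(
                    segment=row["segment"],
                    dominance=row["dominance"],
                    weight=Fraction(row["weight"]),
                    provenance=row.get("provenance") or "user",
                    name=row.get("name") or "",
                ))
        return cls(entries)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["segment", "dominance", "weight", "provenance", "name"])
            for entry in self._entries.values():
                writer.writerow([entry.segment, entry.dominance,
                                 str(entry.weight), entry.provenance, entry.name])

    def lookup(self, segment: str, dominance: str = "right") -> WeightEntry:
        try:
            return self._entries[(str(segment), dominance)]
        except KeyError:
            raise LookupError(
                f"no SYNTAX weight for segment {segment!r} under "
                f"{dominance} dominance"
            ) from None

    def __contains__(self, key) -> bool:
        segment, dominance = key
        return (str(segment), dominance) in self._entries

    def entries(self) -> list:
        return list(self._entries.values())


def syntax_segment_weight(
    segment: str,
    dominance: str = "right",
    table: Optional[SyntaxWeightTable] = None,
) -> WeightEntry:
    """Tabulated weighting factor for a segment, with its provenance tag."""
    if table is None:
        table = SyntaxWeightTable.default()
    return table.lookup(segment, dominance)


# --------------------------------------------------------------------------
# Adverse-characteristic points (directly assigned in SYNTAX; values have no
# published evidence base — user-editable, SYNTAX-style defaults)
# --------------------------------------------------------------------------

DEFAULT_ADVERSE_POINTS = {
    "bifurcation": Fraction(1),
    "trifurcation": Fraction(3),
    "aorto_ostial": Fraction(1),
    "severe_tortuosity": Fraction(2),
    "length_gt_20mm": Fraction(1),
    "heavy_calcification": Fraction(2),
    "thrombus": Fraction(1),
    "diffuse_disease_small_vessels": Fraction(1),
}


@dataclass(frozen=True)
class SyntaxLesionScore:
    """Lesion and adverse components of one SYNTAX lesion score, kept separate."""

    lesion: Lesion
    segment: str
    weight: Fraction
    factor: Fraction
    lesion_type: str
    adverse_component: Fraction = Fraction(0)
    subtrahend: Fraction = Fraction(0)
    warnings: tuple = ()

    @property
    def lesion_component(self) -> Fraction:
        return self.weight * self.factor

    @property
    def value(self) -> Fraction:
        lesion_part = max(Fraction(0), self.lesion_component - self.subtrahend)
        return lesion_part + self.adverse_component


@dataclass
class SyntaxReport:
    lesion_scores: list = field(default_factory=list)
    total: Fraction = Fraction(0)
    lesion_total: Fraction = Fraction(0)
    adverse_total: Fraction = Fraction(0)
    tier: str = "low"
    excluded: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "lesions": [
                {
                    "node": s.lesion.node_id,
                    "segment": s.segment,
                    "type": s.lesion_type,
                    "weight": float(s.weight),
                    "factor": float(s.factor),
                    "lesion_component": float(s.lesion_component),
                    "adverse_component": float(s.adverse_component),
                    "subtrahend": float(s.subtrahend),
                    "value": float(s.value),
                    "warnings": list(s.warnings),
                }
                for s in self.lesion_scores
            ],
            "total": float(self.total),
            "lesion_total": float(self.lesion_total),
            "adverse_total": float(self.adverse_total),
            "tier": self.tier,
            "excluded": [
                {"node": lesion.node_id, "reason": reason}
                for lesion, reason in self.excluded
            ],
            "warnings": list(self.warnings),
        }


def syntax_lesion_score(
    lesion: Lesion,
    table: Optional[SyntaxWeightTable] = None,
    adverse_points: Optional[Mapping[str, Fraction]] = None,
    *,
    dominance: str = "right",
    lesion_only: bool = False,
    segment: Optional[str] = None,
) -> SyntaxLesionScore:
    """Score one eligible lesion: weight x factor (+ adverse points).

    The lesion component and the adverse component are computed and reported
    separately — they are of different origins and are never conflated.  If
    adverse flags are set but no points config is given, this is an explicit
    error (no silent zeros) unless ``lesion_only`` is requested.
    """
    check = lesion_eligibility(lesion, lesion.reference_diameter_mm)
    if not check:
        raise ContractError(
            f"lesion on {lesion.node_id!r} is ineligible ({check.reason})"
        )
    if table is None:
        table = SyntaxWeightTable.default()
    segment = segment if segment is not None else lesion.node_id
    entry = table.lookup(segment, dominance)
    factor = OCCLUSION_FACTOR if lesion.is_occlusion else NONOCCLUSION_FACTOR

    adverse = Fraction(0)
    if not lesion_only and lesion.flags.any_set():
        if adverse_points is None:
            raise ConfigurationError(
                "adverse-characteristic flags are set but no adverse-points "
                "config was provided; pass adverse_points or use lesion_only"
            )
        for flag, is_set in lesion.flags.as_dict().items():
            if is_set:
                adverse += Fraction(adverse_points[flag])
    return SyntaxLesionScore(
        lesion=lesion,
        segment=segment,
        weight=entry.weight,
        factor=factor,
        lesion_type=lesion_type(lesion),
        adverse_component=adverse,
    )


def syntax_adapted_modification(
    score: SyntaxLesionScore,
    preceding_branches: Sequence,
) -> SyntaxLesionScore:
    """Adapted side-branch modification on the lesion component.

    Same contract as the CatLet modification: each preceding side branch's
    weight is subtracted at the lesion's factor; empty list is the identity;
    a subtrahend exceeding the lesion component clamps it to 0 with warning.
    Branches may be Fractions or objects with a ``weight`` attribute
    (e.g. WeightEntry).
    """
    branch_weights = [Fraction(getattr(b, "weight", b)) for b in preceding_branches]
    if not branch_weights:
        return score
    subtrahend = sum(branch_weights, Fraction(0)) * score.factor
    warnings = score.warnings
    if subtrahend > score.lesion_component:
        warnings = warnings + (
            f"modification subtrahend {format_weight(subtrahend)} exceeds "
            f"lesion component {format_weight(score.lesion_component)}; "
            "clamped to 0",
        )
    return replace(score, subtrahend=score.subtrahend + subtrahend,
                   warnings=warnings)


def _segment_for_node(tree: CoronaryTree, node_id: str,
                      table: SyntaxWeightTable, dominance: str) -> str:
    """Resolve a tree node to a weight-table segment: by id, then by name."""
    if (node_id, dominance) in table:
        return node_id
    node = tree.vessels.get(node_id)
    if node is not None and (node.name, dominance) in table:
        return node.name
    # let lookup raise the canonical error, naming the id
    table.lookup(node_id, dominance)
    return node_id  # pragma: no cover


def syntax_total(
    tree: CoronaryTree,
    table: Optional[SyntaxWeightTable] = None,
    adverse_points: Optional[Mapping[str, Fraction]] = None,
    *,
    dominance: str = "right",
    modification: bool = False,
    lesion_only: bool = False,
) -> SyntaxReport:
    """SYNTAX-score a whole tree; lesion and adverse totals reported separately."""
    if table is None:
        table = SyntaxWeightTable.default()
    report = SyntaxReport()
    for lesion in tree.lesions:
        check = lesion_eligibility(lesion, lesion.reference_diameter_mm)
        if not check:
            report.excluded.append((lesion, check.reason))
            continue
        segment = _segment_for_node(tree, lesion.node_id, table, dominance)
        score = syntax_lesion_score(
            lesion, table, adverse_points,
            dominance=dominance, lesion_only=lesion_only, segment=segment,
        )
        if modification and lesion.preceding_branch_ids:
            branches = [
                table.lookup(
                    _segment_for_node(tree, b, table, dominance), dominance
                )
                for b in lesion.preceding_branch_ids
            ]
            score = syntax_adapted_modification(score, branches)
        report.lesion_scores.append(score)
        report.warnings.extend(score.warnings)
    report.lesion_total = sum(
        (max(Fraction(0), s.lesion_component - s.subtrahend)
         for s in report.lesion_scores),
        Fraction(0),
    )
    report.adverse_total = sum(
        (s.adverse_component for s in report.lesion_scores), Fraction(0)
    )
    report.total = report.lesion_total + report.adverse_total
    report.tier = syntax_tertile(report.total)
    return report


def syntax_tertile(score) -> str:
    """SYNTAX tertile tier: low <23, intermediate 23-33, high >=33."""
    if score < 0:
        raise ValueError(f"score must be non-negative, got {score}")
    if score < 23:
        return "low"
    if score >= 33:
        return "high"
    return "intermediate"


# --------------------------------------------------------------------------
# Flow-conservation audit
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConservationFinding:
    """One internal node where w(parent) != sum of daughters."""

    node_id: str
    parent_weight: Fraction
    daughters_weight: Fraction

    def __str__(self) -> str:
        return (f"{self.node_id}: parent weight "
                f"{format_weight(self.parent_weight)} vs daughters "
                f"{format_weight(self.daughters_weight)}")


def syntax_weight_map(
    tree: CoronaryTree,
    table: Optional[SyntaxWeightTable] = None,
    dominance: str = "right",
) -> dict:
    """node_id -> tabulated SYNTAX weight for every node of the tree."""
    if table is None:
        table = SyntaxWeightTable.default()
    return {
        node_id: table.lookup(
            _segment_for_node(tree, node_id, table, dominance), dominance
        ).weight
        for node_id in tree.vessels
    }


def flow_conservation_audit(
    weights: Mapping[str, Fraction],
    tree: CoronaryTree,
) -> list:
    """Check w(parent) = sum of daughters at every internal node.

    ``weights`` maps every tree node to a weight — either a tabulated SYNTAX
    map (see :func:`syntax_weight_map`) or a CatLet-derived map.  Returns one
    finding per violated node; an empty list means the weighting respects the
    law of flow conservation.  Run against the shipped SYNTAX table on an RCA
    topology this flags the RCA segments (parent 1.0 against daughters
    summing above it); run against derived CatLet weights it returns nothing,
    by construction.
    """
    findings = []
    for node_id in tree.vessels:
        kids = tree.children(node_id)
        if not kids:
            continue
        parent_w = Fraction(weights[node_id])
        daughters_w = sum((Fraction(weights[k]) for k in kids), Fraction(0))
        if parent_w != daughters_w:
            findings.append(ConservationFinding(node_id, parent_w, daughters_w))
    return findings
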