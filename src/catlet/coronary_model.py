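"""Coronary-tree data model shared by the CatLet and SYNTAX scoring engines.

The model represents an already-read angiogram description: a forest of
vessel segments (at most three rooted trees — the left main system, an
optional free-standing left system remnant, and the RCA system), lesions
attached to named vessel nodes, and the circulation-pattern label used by
the CatLet weighting scheme.

Myocardial mass is accounted in 17 left-ventricular segments, each one mass
unit; terminal vessels carry the number of segments they supply and the
counts must sum to exactly 17 across the whole forest.  Weights and counts
are kept as :class:`fractions.Fraction` so conservation checks are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "ADVERSE_CHARACTERISTICS",
    "CatletError",
    "ConfigurationError",
    "ContractError",
    "SchemaError",
    "OcclusionClass",
    "AdverseFlags",
    "Lesion",
    "VesselNode",
    "SegmentAllocation",
    "CoronaryTree",
    "Violation",
    "Eligibility",
    "TOTAL_SEGMENTS",
    "MIN_STENOSIS_PCT",
    "MIN_VESSEL_DIAMETER_MM",
    "validate_tree",
    "lesion_eligibility",
    "tree_to_dict",
    "tree_from_dict",
    "as_fraction",
]

# --------------------------------------------------------------------------
# Constants (scoring thresholds shared by both engines)
# --------------------------------------------------------------------------

#: Number of LV segments in the 17-segment myocardial model; 1 segment = 1 mass unit.
TOTAL_SEGMENTS = 17

#: A lesion is scored only at >=50% diameter stenosis ...
MIN_STENOSIS_PCT = 50.0
#: ... on vessels strictly greater than 1.5 mm in diameter.
MIN_VESSEL_DIAMETER_MM = 1.5

#: The eight adverse angiographic characteristics.  CatLet records them
#: qualitatively only; the SYNTAX score attaches configurable points to them.
ADVERSE_CHARACTERISTICS = (
    "bifurcation",
    "trifurcation",
    "aorto_ostial",
    "severe_tortuosity",
    "length_gt_20mm",
    "heavy_calcification",
    "thrombus",
    "diffuse_disease_small_vessels",
)


class CatletError(Exception):
    """Base class for package errors."""


class ConfigurationError(CatletError):
    """A config table (allocation table, weight table, adverse points) is invalid."""


class ContractError(CatletError):
    """A caller violated an operation precondition (e.g. unvalidated tree)."""


class SchemaError(CatletError):
    """An angiogram document failed structural validation; names the failing path."""


def as_fraction(value: Union[int, float, str, Fraction]) -> Fraction:
    """Convert a config/JSON value to an exact Fraction.

    Floats are interpreted through their decimal string form ("3.5" -> 7/2),
    never through their binary expansion, so config files written with one
    decimal place round-trip exactly.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, bool):
        raise TypeError("booleans are not valid counts/weights")
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(str(value))
    if isinstance(value, str):
        return Fraction(value)
    raise TypeError(f"cannot interpret {value!r} as a number")


def _fraction_to_json(value: Fraction) -> Union[int, float, str]:
    if value.denominator == 1:
        return int(value)
    as_float = float(value)
    if Fraction(str(as_float)) == value:  # decimal-exact, safe to emit as number
        return as_float
    return str(value)


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


class OcclusionClass(str, Enum):
    """Occlusion status of a lesion.

    Kept as an explicit class (not inferred from stenosis = 100%) so that
    acute vs chronic total occlusion — distinct lesion types in the six-type
    taxonomy — is preserved.
    """

    NONE = "none"
    ACUTE_TOTAL = "acute_total"
    CHRONIC_TOTAL = "chronic_total"


@dataclass(frozen=True)
class AdverseFlags:
    """The eight adverse-characteristic booleans. Never numeric in CatLet."""

    bifurcation: bool = False
    trifurcation: bool = False
    aorto_ostial: bool = False
    severe_tortuosity: bool = False
    length_gt_20mm: bool = False
    heavy_calcification: bool = False
    thrombus: bool = False
    diffuse_disease_small_vessels: bool = False

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in ADVERSE_CHARACTERISTICS}

    def any_set(self) -> bool:
        return any(self.as_dict().values())

    @classmethod
    def from_dict(cls, data: Mapping[str, bool]) -> "AdverseFlags":
        unknown = set(data) - set(ADVERSE_CHARACTERISTICS)
        if unknown:
            raise SchemaError(
                f"unknown adverse-characteristic flag(s): {sorted(unknown)}"
            )
        return cls(**{k: bool(v) for k, v in data.items()})


@dataclass(frozen=True)
class Lesion:
    """A single lesion attached to one vessel node.

    A lesion spanning several segments is entered as several lesions (the
    model deliberately binds one lesion to one node).  ``preceding_branch_ids``
    names side branches arising proximal to the lesion on the same vessel;
    they drive the adapted scoring modification.
    """

    node_id: str
    stenosis_pct: float
    occlusion: OcclusionClass = OcclusionClass.NONE
    in_stent: bool = False
    reference_diameter_mm: float = 3.0
    flags: AdverseFlags = field(default_factory=AdverseFlags)
    culprit: bool = False
    preceding_branch_ids: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "occlusion", OcclusionClass(self.occlusion))
        object.__setattr__(
            self, "preceding_branch_ids", tuple(self.preceding_branch_ids)
        )

    @property
    def is_occlusion(self) -> bool:
        return self.occlusion is not OcclusionClass.NONE


@dataclass
class VesselNode:
    """A vessel segment in the coronary forest.

    ``segments_supplied`` is set on terminal nodes only: the number of LV
    segments (mass units) the vessel supplies.  Identifiers are strings so
    suffixed segment numbers (``16a`` ...) are admissible.
    """

    id: str
    name: str = ""
    parent: Optional[str] = None
    segments_supplied: Optional[Fraction] = None
    diameter_mm: Optional[float] = None

    def __post_init__(self):
        if self.segments_supplied is not None:
            self.segments_supplied = as_fraction(self.segments_supplied)


@dataclass(frozen=True)
class SegmentAllocation:
    """Per-terminal-vessel supplied-segment counts over the 17-segment model.

    Invariants: every count >= 0 and the counts sum to exactly 17.
    """

    counts: Mapping[str, Fraction]

    def __post_init__(self):
        counts = {k: as_fraction(v) for k, v in dict(self.counts).items()}
        object.__setattr__(self, "counts", counts)
        for vessel, count in counts.items():
            if count < 0:
                raise ConfigurationError(
                    f"segment allocation for {vessel!r} is negative ({count})"
                )
        if self.total != TOTAL_SEGMENTS:
            raise ConfigurationError(
                f"segment allocation sums to {self.total}, not {TOTAL_SEGMENTS}"
            )

    @property
    def total(self) -> Fraction:
        return sum(self.counts.values(), Fraction(0))

    def __getitem__(self, vessel: str) -> Fraction:
        return self.counts[vessel]


@dataclass
class CoronaryTree:
    """The vessel forest with its lesions and circulation-pattern reference."""

    vessels: dict = field(default_factory=dict)  # id -> VesselNode, insertion-ordered
    lesions: list = field(default_factory=list)
    pattern: object = None  # a pattern_weights.CirculationPattern, if known

    # -- structure helpers -------------------------------------------------

    def roots(self) -> list:
        return [v.id for v in self.vessels.values() if v.parent is None]

    def children(self, node_id: str) -> list:
        return [v.id for v in self.vessels.values() if v.parent == node_id]

    def is_terminal(self, node_id: str) -> bool:
        return not self.children(node_id)

    def terminal_ids(self) -> list:
        have_children = {v.parent for v in self.vessels.values() if v.parent}
        return [i for i in self.vessels if i not in have_children]

    def add_vessel(self, node: VesselNode) -> "CoronaryTree":
        self.vessels[node.id] = node
        return self

    def add_lesion(self, lesion: Lesion) -> "CoronaryTree":
        self.lesions.append(lesion)
        return self

    def segment_allocation(self) -> SegmentAllocation:
        """The allocation implied by the terminal supplied-segment counts."""
        counts = {}
        for tid in self.terminal_ids():
            count = self.vessels[tid].segments_supplied
            counts[tid] = Fraction(0) if count is None else count
        return SegmentAllocation(counts)


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    """A single broken invariant: which node, which rule, human message."""

    node_id: str
    rule: str
    message: str

    def __str__(self) -> str:
        return f"[{self.rule}] {self.node_id}: {self.message}"


def validate_tree(tree: CoronaryTree) -> list:
    """Check every CoronaryTree invariant; return a list of violations.

    An empty list means the tree is well formed: parent links resolve with no
    cycles, the forest has at most three roots, every lesion sits on an
    existing node, terminal counts are non-negative and conserve the 17 mass
    units, and each lesion's fields are internally consistent.
    """
    violations: list = []
    ids = set(tree.vessels)

    for node in tree.vessels.values():
        if node.parent is not None and node.parent not in ids:
            violations.append(
                Violation(node.id, "dangling-parent",
                          f"parent {node.parent!r} does not exist")
            )

    # cycle detection along parent links
    for node in tree.vessels.values():
        seen = {node.id}
        cur = node.parent
        while cur is not None and cur in ids:
            if cur in seen:
                violations.append(
                    Violation(node.id, "cycle", f"parent chain revisits {cur!r}")
                )
                break
            seen.add(cur)
            cur = tree.vessels[cur].parent

    roots = tree.roots()
    if len(roots) > 3:
        violations.append(
            Violation(",".join(roots), "forest-size",
                      f"{len(roots)} rooted trees; at most 3 allowed")
        )

    terminal_ids = set(tree.terminal_ids())
    total = Fraction(0)
    any_counts = False
    for node in tree.vessels.values():
        count = node.segments_supplied
        if count is None:
            continue
        if node.id not in terminal_ids:
            violations.append(
                Violation(node.id, "internal-count",
                          "segments_supplied set on a non-terminal node")
            )
            continue
        any_counts = True
        if count < 0:
            violations.append(
                Violation(node.id, "negative-count",
                          f"supplied-segment count {count} is negative")
            )
        total += count
    if any_counts and total != TOTAL_SEGMENTS and not any(
        v.rule in ("dangling-parent", "cycle") for v in violations
    ):
        violations.append(
            Violation("<forest>", "17-unit-conservation",
                      f"terminal supplied-segment counts sum to {total}, "
                      f"not {TOTAL_SEGMENTS}")
        )

    for i, lesion in enumerate(tree.lesions):
        tag = f"lesion[{i}]"
        if lesion.node_id not in ids:
            violations.append(
                Violation(lesion.node_id, "lesion-node",
                          f"{tag} attached to nonexistent node "
                          f"{lesion.node_id!r}")
            )
        if not (0.0 <= lesion.stenosis_pct <= 100.0):
            violations.append(
                Violation(lesion.node_id, "stenosis-range",
                          f"{tag} stenosis {lesion.stenosis_pct}% outside [0, 100]")
            )
        if lesion.is_occlusion and lesion.stenosis_pct != 100.0:
            violations.append(
                Violation(lesion.node_id, "occlusion-stenosis",
                          f"{tag} occlusion class {lesion.occlusion.value} "
                          f"requires stenosis 100%, got {lesion.stenosis_pct}%")
            )
        for branch in lesion.preceding_branch_ids:
            if branch not in ids:
                violations.append(
                    Violation(branch, "preceding-branch",
                              f"{tag} names nonexistent preceding branch "
                              f"{branch!r}")
                )

    return violations


@dataclass(frozen=True)
class Eligibility:
    eligible: bool
    reasons: tuple = ()

    @property
    def reason(self) -> Optional[str]:
        return "; ".join(self.reasons) if self.reasons else None

    def __bool__(self) -> bool:
        return self.eligible


def lesion_eligibility(lesion: Lesion, vessel_diameter_mm: float) -> Eligibility:
    """Scoring eligibility: >=50% diameter stenosis on a vessel >1.5 mm.

    The diameter bound is strict and the stenosis bound inclusive.  The
    returned reasons name every failed criterion.
    """
    if vessel_diameter_mm <= 0:
        raise ValueError(f"vessel diameter must be positive, got {vessel_diameter_mm}")
    if not (0.0 <= lesion.stenosis_pct <= 100.0):
        raise ValueError(f"stenosis {lesion.stenosis_pct}% outside [0, 100]")
    reasons = []
    if lesion.stenosis_pct < MIN_STENOSIS_PCT:
        reasons.append("stenosis below 50%")
    if not vessel_diameter_mm > MIN_VESSEL_DIAMETER_MM:
        reasons.append("vessel not >1.5 mm")
    return Eligibility(eligible=not reasons, reasons=tuple(reasons))


# --------------------------------------------------------------------------
# Serialization (angiogram document <-> model); file IO lives in cli_io
# --------------------------------------------------------------------------

SCHEMA_VERSION = "1"


def tree_to_dict(tree: CoronaryTree) -> dict:
    """Serialize to the angiogram document structure (schema version 1)."""
    pattern = None
    if tree.pattern is not None:
        pattern = {
            "rca_type": tree.pattern.rca_type,
            "lad_type": tree.pattern.lad_type,
            "dx_type": tree.pattern.dx_type,
        }
    vessels = []
    for node in tree.vessels.values():
        entry = {"id": node.id, "name": node.name, "parent": node.parent}
        if node.segments_supplied is not None:
            entry["segments_supplied"] = _fraction_to_json(node.segments_supplied)
        if node.diameter_mm is not None:
            entry["diameter_mm"] = node.diameter_mm
        vessels.append(entry)
    lesions = []
    for lesion in tree.lesions:
        lesions.append({
            "node": lesion.node_id,
            "stenosis_pct": lesion.stenosis_pct,
            "occlusion": lesion.occlusion.value,
            "in_stent": lesion.in_stent,
            "reference_diameter_mm": lesion.reference_diameter_mm,
            "flags": lesion.flags.as_dict(),
            "culprit": lesion.culprit,
            "preceding_branches": list(lesion.preceding_branch_ids),
        })
    return {
        "schema_version": SCHEMA_VERSION,
        "pattern": pattern,
        "vessels": vessels,
        "lesions": lesions,
    }


def _require(condition: bool, path: str, message: str) -> None:
    if not condition:
        raise SchemaError(f"{path}: {message}")


def tree_from_dict(data: Mapping) -> CoronaryTree:
    """Parse an angiogram document; raises SchemaError naming the first failing path."""
    _require(isinstance(data, Mapping), "$", "document must be a JSON object")
    version = data.get("schema_version", SCHEMA_VERSION)
    _require(str(version) == SCHEMA_VERSION, "$.schema_version",
             f"unsupported schema version {version!r} (supported: {SCHEMA_VERSION})")

    vessels_raw = data.get("vessels")
    _require(isinstance(vessels_raw, Sequence) and not isinstance(vessels_raw, str),
             "$.vessels", "must be an array of vessel objects")
    _require(len(vessels_raw) > 0, "$.vessels", "vessels array is empty")

    tree = CoronaryTree()
    for i, raw in enumerate(vessels_raw):
        path = f"$.vessels[{i}]"
        _require(isinstance(raw, Mapping), path, "must be an object")
        _require("id" in raw, path, "missing required key 'id'")
        try:
            node = VesselNode(
                id=str(raw["id"]),
                name=str(raw.get("name", "")),
                parent=None if raw.get("parent") is None else str(raw["parent"]),
                segments_supplied=(
                    None if raw.get("segments_supplied") is None
                    else as_fraction(raw["segments_supplied"])
                ),
                diameter_mm=(
                    None if raw.get("diameter_mm") is None
                    else float(raw["diameter_mm"])
                ),
            )
        except (ValueError, TypeError, ZeroDivisionError) as exc:
            raise SchemaError(f"{path}: {exc}") from exc
        _require(node.id not in tree.vessels, path, f"duplicate vessel id {node.id!r}")
        tree.add_vessel(node)

    lesions_raw = data.get("lesions", [])
    _require(isinstance(lesions_raw, Sequence) and not isinstance(lesions_raw, str),
             "$.lesions", "must be an array of lesion objects")
    for i, raw in enumerate(lesions_raw):
        path = f"$.lesions[{i}]"
        _require(isinstance(raw, Mapping), path, "must be an object")
        for key in ("node", "stenosis_pct"):
            _require(key in raw, path, f"missing required key {key!r}")
        try:
            lesion = Lesion(
                node_id=str(raw["node"]),
                stenosis_pct=float(raw["stenosis_pct"]),
                occlusion=OcclusionClass(raw.get("occlusion", "none")),
                in_stent=bool(raw.get("in_stent", False)),
                reference_diameter_mm=float(raw.get("reference_diameter_mm", 3.0)),
                flags=AdverseFlags.from_dict(raw.get("flags", {})),
                culprit=bool(raw.get("culprit", False)),
                preceding_branch_ids=tuple(
                    str(b) for b in raw.get("preceding_branches", [])
                ),
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: {exc}") from exc
        tree.add_lesion(lesion)

    pattern_raw = data.get("pattern")
    if pattern_raw is not None:
        path = "$.pattern"
        _require(isinstance(pattern_raw, Mapping), path, "must be an object")
        from .pattern_weights import classify_pattern  # deferred: avoids cycle

        try:
            tree.pattern = classify_pattern(
                pattern_raw.get("rca_type"),
                pattern_raw.get("lad_type"),
                pattern_raw.get("dx_type"),
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: {exc}") from exc
    return tree
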