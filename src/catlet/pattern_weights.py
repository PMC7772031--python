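"""Circulation-pattern classification and conservation-respecting vessel weights.

The coronary circulation pattern is classified on three axes — the RCA into
six progressively larger types (PDA zero, PDA only, small, average, large,
super), the LAD into three (short, average, long) and the diagonal system
into three (small, intermediate, large) — giving 54 pattern types in place
of the classical right/left dominance dichotomy.

Each pattern maps, through an editable allocation table, to supplied-segment
counts over the 17-segment LV model.  Vessel weighting then follows two
laws:

* law of flow conservation — a parent vessel's weight equals the sum of its
  daughters' weights (terminal weight = segments supplied);
* law of competitive blood supply — the LCX territory is whatever the RCA,
  LAD and diagonals do not take: LCX = 17 − (LAD + Dx + PDA + PLV).

The shipped default allocation table is a stand-in constructed from those
laws (monotone counts along each axis); it is NOT the canonical published
matrix, and can be replaced wholesale via :func:`load_allocation_table`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .coronary_model import (
    TOTAL_SEGMENTS,
    ConfigurationError,
    ContractError,
    CoronaryTree,
    SegmentAllocation,
    as_fraction,
    validate_tree,
)

__all__ = [
    "RCA_TYPES",
    "LAD_TYPES",
    "DX_TYPES",
    "CirculationPattern",
    "VesselWeight",
    "classify_pattern",
    "enumerate_patterns",
    "default_allocation_table",
    "load_allocation_table",
    "write_allocation_table",
    "allocate_segments",
    "derive_vessel_weights",
    "format_weight",
]

RCA_TYPES = ("PDA zero", "PDA only", "small RCA", "average RCA",
             "large RCA", "super RCA")
LAD_TYPES = ("short", "average", "long")
DX_TYPES = ("small", "intermediate", "large")


@dataclass(frozen=True)
class CirculationPattern:
    """One of the 54 (RCA-type, LAD-type, Dx-type) circulation patterns."""

    rca_type: str
    lad_type: str
    dx_type: str

    def __post_init__(self):
        _check_axis("rca_type", self.rca_type, RCA_TYPES)
        _check_axis("lad_type", self.lad_type, LAD_TYPES)
        _check_axis("dx_type", self.dx_type, DX_TYPES)

    def as_tuple(self) -> tuple:
        return (self.rca_type, self.lad_type, self.dx_type)

    def __str__(self) -> str:
        return f"{self.rca_type} / LAD {self.lad_type} / Dx {self.dx_type}"


@dataclass(frozen=True)
class VesselWeight:
    """A vessel's weighting factor in mass units (dimensionless)."""

    vessel_id: str
    weight: Fraction

    def __post_init__(self):
        object.__setattr__(self, "weight", as_fraction(self.weight))
        if self.weight < 0:
            raise ValueError(f"weight for {self.vessel_id!r} is negative")


def _check_axis(axis: str, value, admissible: tuple) -> None:
    if value not in admissible:
        raise ValueError(
            f"unknown {axis} {value!r}; expected one of {list(admissible)}"
        )


def classify_pattern(rca_type: str, lad_type: str, dx_type: str) -> CirculationPattern:
    """Validate the three pre-judged axis categories into a pattern.

    Classification consumes categories already judged by the angiographer;
    no attempt is made to infer them from measurements.  Unknown category
    strings raise ValueError naming the offending axis.
    """
    return CirculationPattern(rca_type, lad_type, dx_type)


def enumerate_patterns(
    rca_types: Sequence[str] = RCA_TYPES,
    lad_types: Sequence[str] = LAD_TYPES,
    dx_types: Sequence[str] = DX_TYPES,
) -> list:
    """All distinct patterns in canonical (axis-declaration) order.

    The full cross-product has 6 x 3 x 3 = 54 members; freezing an axis to a
    subset enumerates the corresponding slice.  Order is stable across runs.
    """
    return [
        CirculationPattern(r, l, d)
        for r, l, d in product(rca_types, lad_types, dx_types)
    ]


# --------------------------------------------------------------------------
# Allocation table: pattern -> supplied-segment counts
# --------------------------------------------------------------------------

# Stand-in defaults built from the stated laws (monotone along each axis);
# the canonical published matrix can be dropped in via load_allocation_table.
_RCA_SPLITS = {                 # rca_type -> (PDA, PLV) counts
    "PDA zero": (0, 0),
    "PDA only": (1, 0),         # "PDA only" read as PLV count exactly 0
    "small RCA": (2, 1),
    "average RCA": (2, 2),
    "large RCA": (3, 2),
    "super RCA": (3, 3),
}
_LAD_COUNTS = {"short": 6, "average": 7, "long": 8}
_DX_COUNTS = {"small": 1, "intermediate": 2, "large": 3}

ALLOCATION_COLUMNS = ("LAD", "Dx", "PDA", "PLV")


def default_allocation_table() -> dict:
    """The shipped (non-canonical) allocation table over all 54 patterns.

    Keys are (rca_type, lad_type, dx_type) tuples; values map vessel labels
    LAD/Dx/PDA/PLV to integer segment counts.  LCX is never stored — it is
    the residual under the law of competitive blood supply.
    """
    table = {}
    for pattern in enumerate_patterns():
        pda, plv = _RCA_SPLITS[pattern.rca_type]
        table[pattern.as_tuple()] = {
            "LAD": Fraction(_LAD_COUNTS[pattern.lad_type]),
            "Dx": Fraction(_DX_COUNTS[pattern.dx_type]),
            "PDA": Fraction(pda),
            "PLV": Fraction(plv),
        }
    return table


def load_allocation_table(path) -> dict:
    """Read an allocation table CSV: rca_type,lad_type,dx_type,LAD,Dx,PDA,PLV[,LCX].

    An explicit LCX column, when present, must make each full row sum to 17;
    otherwise LCX is computed as the residual at allocation time.
    """
    table = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        missing = [c for c in ("rca_type", "lad_type", "dx_type", *ALLOCATION_COLUMNS)
                   if c not in fields]
        if missing:
            raise ConfigurationError(
                f"allocation table {path} missing column(s) {missing}"
            )
        for row in reader:
            key = (row["rca_type"], row["lad_type"], row["dx_type"])
            counts = {c: as_fraction(row[c]) for c in ALLOCATION_COLUMNS}
            if fields and "LCX" in fields and row.get("LCX") not in (None, ""):
                counts["LCX"] = as_fraction(row["LCX"])
            table[key] = counts
    return table


def write_allocation_table(path, table: Optional[Mapping] = None) -> None:
    """Write an allocation table (default: the shipped one) as editable CSV."""
    if table is None:
        table = default_allocation_table()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rca_type", "lad_type", "dx_type", *ALLOCATION_COLUMNS])
        for key in sorted(table, key=_pattern_sort_key):
            row = table[key]
            writer.writerow([*key, *(str(row[c]) for c in ALLOCATION_COLUMNS)])


def _pattern_sort_key(key: tuple) -> tuple:
    r, l, d = key
    return (RCA_TYPES.index(r), LAD_TYPES.index(l), DX_TYPES.index(d))


def allocate_segments(
    pattern: CirculationPattern,
    allocation_table: Optional[Mapping] = None,
) -> SegmentAllocation:
    """Supplied-segment counts for LAD, Dx, PDA, PLV and (residual) LCX.

    The LCX count follows the law of competitive blood supply:
    LCX = 17 − (LAD + Dx + PDA + PLV).  A table row with an explicit LCX
    column must instead sum to exactly 17.  Any negative count is a
    configuration error identifying the pattern.
    """
    if allocation_table is None:
        allocation_table = default_allocation_table()
    key = pattern.as_tuple()
    if key not in allocation_table:
        raise ConfigurationError(f"allocation table has no row for pattern {key}")
    row = allocation_table[key]
    counts = {c: as_fraction(row[c]) for c in ALLOCATION_COLUMNS}
    explicit_total = sum(counts.values(), Fraction(0))
    if "LCX" in row:
        lcx = as_fraction(row["LCX"])
        if explicit_total + lcx != TOTAL_SEGMENTS:
            raise ConfigurationError(
                f"allocation row for pattern {key} sums to "
                f"{explicit_total + lcx}, not {TOTAL_SEGMENTS}"
            )
    else:
        lcx = TOTAL_SEGMENTS - explicit_total
    if lcx < 0:
        raise ConfigurationError(
            f"allocation row for pattern {key} leaves negative LCX ({lcx})"
        )
    counts["LCX"] = lcx
    for vessel, count in counts.items():
        if count < 0:
            raise ConfigurationError(
                f"allocation row for pattern {key} has negative {vessel} ({count})"
            )
    return SegmentAllocation(counts)


# --------------------------------------------------------------------------
# Weight derivation under the law of flow conservation
# --------------------------------------------------------------------------


def derive_vessel_weights(
    tree: CoronaryTree,
    allocation: Optional[SegmentAllocation] = None,
) -> dict:
    """Per-node weighting factors, bottom-up: terminal = its supplied-segment
    count; internal = sum of its daughters.  Exact Fractions throughout.

    The tree must pass :func:`validate_tree`; when an allocation is given,
    terminal counts are checked against it (matching on terminal node id,
    then node name).
    """
    violations = validate_tree(tree)
    if violations:
        raise ContractError(
            "derive_vessel_weights requires a valid tree; violations: "
            + "; ".join(str(v) for v in violations)
        )
    if allocation is not None:
        for tid in tree.terminal_ids():
            node = tree.vessels[tid]
            expected = allocation.counts.get(tid, allocation.counts.get(node.name))
            have = node.segments_supplied or Fraction(0)
            if expected is not None and have != expected:
                raise ContractError(
                    f"terminal {tid!r} supplies {have} segments but the "
                    f"allocation assigns {expected}"
                )

    children: dict = {vid: [] for vid in tree.vessels}
    for node in tree.vessels.values():
        if node.parent is not None:
            children[node.parent].append(node.id)

    weights: dict = {}

    def visit(node_id: str) -> Fraction:
        kids = children[node_id]
        if not kids:
            w = tree.vessels[node_id].segments_supplied or Fraction(0)
        else:
            w = sum((visit(k) for k in kids), Fraction(0))
        weights[node_id] = w
        return w

    for root in tree.roots():
        visit(root)
    return weights


def format_weight(weight: Fraction) -> str:
    """Format a weight to one decimal place ("7.0", "3.5" style)."""
    return f"{float(weight):.1f}"
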