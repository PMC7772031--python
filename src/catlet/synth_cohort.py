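"""Seeded synthetic generators: coronary trees, rater pairs, outcome cohorts.

Everything here is test scaffolding: it emulates the *structure* of
angiographic data (circulation patterns over the 54 types, lesion burdens,
paired observer ratings with controllable disagreement, score+outcome
cohorts), not clinical lesion epidemiology.  All generators are pure
functions of a :class:`GeneratorSpec` — same spec, same output, bit for bit.
The pseudo-random generator is pinned to numpy's PCG64 so fixtures reproduce
across platforms.

Distributional choices (uniform pattern draw, stenosis uniform on [50, 99],
occlusions split evenly acute/chronic, independent Bernoulli flags) are
deliberate simplifications; see the methods note for what they do and do not
exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .coronary_model import (
    AdverseFlags,
    ADVERSE_CHARACTERISTICS,
    CoronaryTree,
    Lesion,
    OcclusionClass,
    VesselNode,
)
from .pattern_weights import (
    CirculationPattern,
    allocate_segments,
    enumerate_patterns,
)

__all__ = [
    "GeneratorSpec",
    "build_skeleton",
    "generate_tree",
    "generate_trees",
    "generate_rating_pairs",
    "generate_outcome_cohort",
]

#: Pinned generator algorithm; fixtures are reproducible across platforms.
RNG_ALGORITHM = "PCG64"


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))


@dataclass(frozen=True)
class GeneratorSpec:
    """All knobs for the three generators; identical spec => identical output.

    ``lesion_rate`` is the expected number of eligible lesions per tree
    (Poisson).  ``disagreement_rate`` is the per-item probability that rater
    B's rating is flipped to a different category.  ``event_probs`` are the
    per-tier event probabilities (monotone in tier) for the outcome model;
    ``shift_strength`` is the outcome-correlated signed shift applied to the
    new score (0 = null: the new score adds only symmetric noise).
    """

    seed: int = 0
    n: int = 100
    lesion_rate: float = 2.0
    occlusion_prob: float = 0.25
    in_stent_prob: float = 0.1
    flag_prob: float = 0.15
    modification_prob: float = 0.3
    disagreement_rate: float = 0.2
    n_categories: int = 3
    event_probs: tuple = (0.05, 0.15, 0.30)
    shift_strength: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.disagreement_rate <= 1.0:
            raise ValueError("disagreement_rate must be in [0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.event_probs):
            raise ValueError("event probabilities must be in [0, 1]")
        if list(self.event_probs) != sorted(self.event_probs):
            raise ValueError("event probabilities must be monotone in tier")


# --------------------------------------------------------------------------
# Coronary trees
# --------------------------------------------------------------------------

# Fixed forest skeleton (SYNTAX segment numbering); terminal nodes carry the
# pattern's supplied-segment counts.
_SKELETON = (
    # id, name, parent
    ("5", "Left main", None),
    ("6", "LAD proximal", "5"),
    ("7", "LAD mid", "6"),
    ("8", "LAD apical", "7"),
    ("9", "First diagonal", "6"),
    ("11", "LCX proximal", "5"),
    ("13", "LCX distal", "11"),
    ("1", "RCA proximal", None),
    ("2", "RCA mid", "1"),
    ("3", "RCA distal", "2"),
    ("4", "Posterior descending artery", "3"),
    ("16", "Posterolateral branch from the RCA", "3"),
)

#: terminal node id -> allocation label
_TERMINALS = {"8": "LAD", "9": "Dx", "13": "LCX", "4": "PDA", "16": "PLV"}


def build_skeleton(pattern: CirculationPattern,
                   allocation_table=None) -> CoronaryTree:
    """A two-rooted coronary forest realising a pattern's segment allocation."""
    allocation = allocate_segments(pattern, allocation_table)
    tree = CoronaryTree(pattern=pattern)
    for vid, name, parent in _SKELETON:
        count = allocation[_TERMINALS[vid]] if vid in _TERMINALS else None
        tree.add_vessel(VesselNode(id=vid, name=name, parent=parent,
                                   segments_supplied=count))
    return tree


def generate_tree(spec: GeneratorSpec,
                  rng: Optional[np.random.Generator] = None) -> CoronaryTree:
    """One random valid tree: uniform pattern over the 54 types, Poisson
    lesion count, stenosis uniform on [50, 99] or occlusion at 100%."""
    if rng is None:
        rng = _rng(spec.seed)
    patterns = enumerate_patterns()
    pattern = patterns[int(rng.integers(len(patterns)))]
    tree = build_skeleton(pattern)

    node_ids = list(tree.vessels)
    n_lesions = int(rng.poisson(spec.lesion_rate))
    for _ in range(n_lesions):
        node_id = node_ids[int(rng.integers(len(node_ids)))]
        occluded = rng.random() < spec.occlusion_prob
        if occluded:
            stenosis = 100.0
            occlusion = (OcclusionClass.ACUTE_TOTAL if rng.random() < 0.5
                         else OcclusionClass.CHRONIC_TOTAL)
        else:
            stenosis = float(rng.integers(50, 100))
            occlusion = OcclusionClass.NONE
        flags = AdverseFlags(**{
            name: bool(rng.random() < spec.flag_prob)
            for name in ADVERSE_CHARACTERISTICS
        })
        # exercise the adapted modification on proximal-LAD lesions
        preceding = ()
        if node_id == "6" and rng.random() < spec.modification_prob:
            preceding = ("9",)
        tree.add_lesion(Lesion(
            node_id=node_id,
            stenosis_pct=stenosis,
            occlusion=occlusion,
            in_stent=bool(rng.random() < spec.in_stent_prob),
            reference_diameter_mm=float(np.round(rng.uniform(2.0, 4.0), 2)),
            flags=flags,
            culprit=bool(n_lesions > 0 and rng.random() < 0.2),
            preceding_branch_ids=preceding,
        ))
    return tree


def generate_trees(spec: GeneratorSpec) -> list:
    """``spec.n`` trees from one seeded stream (deterministic in spec)."""
    rng = _rng(spec.seed)
    return [generate_tree(spec, rng) for _ in range(spec.n)]


# --------------------------------------------------------------------------
# Paired observer ratings (reproducibility studies)
# --------------------------------------------------------------------------


def generate_rating_pairs(spec: GeneratorSpec):
    """Two ordinal rating sequences over ``n_categories`` categories.

    Rater A rates uniformly; rater B repeats A's rating except that with
    probability ``disagreement_rate`` the item is flipped to one of the other
    categories, uniformly.  At rate 0 the two sequences are identical
    (kappa = 1 exactly).
    """
    rng = _rng(spec.seed)
    k = spec.n_categories
    a = rng.integers(0, k, size=spec.n)
    b = a.copy()
    flip = rng.random(spec.n) < spec.disagreement_rate
    if k > 1:
        offsets = rng.integers(1, k, size=spec.n)  # 1..k-1: always a change
        b[flip] = (a[flip] + offsets[flip]) % k
    return a, b


# --------------------------------------------------------------------------
# Score + outcome cohorts (reclassification studies)
# --------------------------------------------------------------------------


def generate_outcome_cohort(spec: GeneratorSpec):
    """(old_scores, new_scores, outcomes) for NRI studies.

    Old scores are uniform on [0, 40]; outcomes are Bernoulli with the
    tier-dependent probabilities of ``event_probs`` (tiers cut at the CatLet
    tertiles).  New scores are old + N(0, noise_sd) + shift_strength signed
    by outcome: at strength 0 the expected NRI is 0; at large strength the
    separation is effectively deterministic and NRI -> 2.
    """
    rng = _rng(spec.seed)
    old = rng.uniform(0.0, 40.0, size=spec.n)
    tier_idx = np.digitize(old, [9.0, 15.0], right=True)  # CatLet tertile cuts
    p_event = np.asarray(spec.event_probs)[tier_idx]
    outcomes = (rng.random(spec.n) < p_event).astype(int)
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n)
    new = old + noise + spec.shift_strength * (2 * outcomes - 1)
    return old, new, outcomes
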