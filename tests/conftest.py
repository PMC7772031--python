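from fractions import Fraction

import pytest

from catlet import (
    AdverseFlags,
    CoronaryTree,
    Lesion,
    OcclusionClass,
    VesselNode,
    derive_vessel_weights,
    figure2_fixture_path,
    read_angiogram,
)


@pytest.fixture
def figure2_tree():
    """The shipped proximal-LAD-occlusion worked-example case."""
    return read_angiogram(figure2_fixture_path())


@pytest.fixture
def figure2_weights(figure2_tree):
    return derive_vessel_weights(figure2_tree)


@pytest.fixture
def simple_tree():
    """A small valid two-lesion forest with integer terminal counts (sum 17)."""
    tree = CoronaryTree()
    tree.add_vessel(VesselNode("LM", "Left main", None))
    tree.add_vessel(VesselNode("LAD", "LAD", "LM", segments_supplied=7))
    tree.add_vessel(VesselNode("Dx", "Diagonal", "LM", segments_supplied=2))
    tree.add_vessel(VesselNode("LCX", "LCX", "LM", segments_supplied=4))
    tree.add_vessel(VesselNode("RCA", "RCA", None))
    tree.add_vessel(VesselNode("PDA", "PDA", "RCA", segments_supplied=2))
    tree.add_vessel(VesselNode("PLV", "PLV", "RCA", segments_supplied=2))
    tree.add_lesion(Lesion("LAD", 100.0, OcclusionClass.CHRONIC_TOTAL,
                           reference_diameter_mm=3.0))
    tree.add_lesion(Lesion("PDA", 60.0, reference_diameter_mm=2.5))
    return tree


@pytest.fixture
def halfweight_tree():
    """A tree whose lesioned vessel derives weight 3.5 with a preceding
    1.0-weight side branch — the worked modification arithmetic
    (3.5 x 5 − 1.0 x 5 = 12.5) expressed in CatLet-derived weights."""
    tree = CoronaryTree()
    tree.add_vessel(VesselNode("prox", "Proximal vessel", None))
    tree.add_vessel(VesselNode("main", "Main branch", "prox",
                               segments_supplied=Fraction(7, 2)))
    tree.add_vessel(VesselNode("branch", "Side branch", "prox",
                               segments_supplied=Fraction(1)))
    tree.add_vessel(VesselNode("rest", "Remaining territory", None,
                               segments_supplied=Fraction(25, 2)))
    tree.add_lesion(Lesion("main", 100.0, OcclusionClass.CHRONIC_TOTAL,
                           reference_diameter_mm=3.0,
                           preceding_branch_ids=("branch",)))
    return tree


# ---------------------------------------------------------------------------
# Statistics fixtures (small enough to hand-enumerate)
# ---------------------------------------------------------------------------


@pytest.fixture
def kappa_fixture():
    """20 paired ratings over 3 ordered categories."""
    a = [0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 0, 1, 2, 1, 0, 2, 1, 0, 2, 1]
    b = [0, 1, 0, 1, 2, 1, 0, 2, 2, 1, 0, 1, 2, 2, 0, 2, 1, 1, 2, 0]
    return a, b


@pytest.fixture
def nri_fixture():
    """12 subjects: old score, new score, binary outcome."""
    old = [10, 12, 5, 30, 22, 18, 7, 25, 14, 9, 33, 20]
    new = [15, 11, 5, 35, 20, 19, 6, 30, 14, 12, 28, 26]
    outcomes = [1, 0, 0, 1, 1, 0, 0, 1, 0, 1, 1, 0]
    return old, new, outcomes


@pytest.fixture
def reclass_fixture():
    """30 subjects: old tier, new tier, binary outcome."""
    tiers = ("low", "intermediate", "high")
    old = [tiers[i] for i in
           [0, 0, 1, 2, 1, 0, 2, 1, 0, 2, 1, 1, 0, 2, 0,
            1, 2, 0, 1, 2, 0, 1, 2, 1, 0, 2, 1, 0, 1, 2]]
    new = [tiers[i] for i in
           [1, 0, 2, 2, 0, 0, 1, 1, 0, 2, 2, 0, 1, 2, 0,
            1, 2, 1, 0, 1, 0, 2, 2, 1, 1, 2, 0, 0, 1, 2]]
    outcomes = [1, 0, 1, 1, 0, 0, 0, 1, 0, 1, 1, 0, 0, 1, 0,
                1, 1, 0, 0, 0, 1, 1, 0, 0, 0, 1, 0, 0, 1, 1]
    return old, new, outcomes
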