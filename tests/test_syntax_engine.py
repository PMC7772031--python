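"""SYNTAX weights, lesion scoring, modification, tertiles, conservation audit."""

from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from catlet import (
    CoronaryTree,
    DEFAULT_ADVERSE_POINTS,
    AdverseFlags,
    Lesion,
    OcclusionClass,
    SyntaxWeightTable,
    VesselNode,
    catlet_risk_tier,
    derive_vessel_weights,
    enumerate_patterns,
    flow_conservation_audit,
    syntax_adapted_modification,
    syntax_lesion_score,
    syntax_segment_weight,
    syntax_tertile,
    syntax_total,
    syntax_weight_map,
)
from catlet.coronary_model import ConfigurationError, ContractError
from catlet.synth_cohort import build_skeleton


def _lesion(node, stenosis=60.0, occlusion=OcclusionClass.NONE, **kw):
    if occlusion is not OcclusionClass.NONE:
        stenosis = 100.0
    return Lesion(node, stenosis, occlusion, **kw)


class TestWeightTable:
    @pytest.mark.parametrize("segment, weight", [
        ("1", 1), ("2", 1), ("3", 1), ("4", 1),
        ("16", Fraction(1, 2)), ("16a", Fraction(1, 2)),
        ("16b", Fraction(1, 2)), ("16c", Fraction(1, 2)),
    ])
    def test_rca_right_dominance_rows(self, segment, weight):
        entry = syntax_segment_weight(segment, "right")
        assert entry.weight == weight
        assert entry.provenance == "rca_table"

    def test_proximal_lad_is_3_5(self):
        entry = syntax_segment_weight("6", "right")
        assert entry.weight == Fraction(7, 2)
        assert entry.provenance == "standard"

    def test_unknown_segment_names_it(self):
        with pytest.raises(LookupError, match="99"):
            syntax_segment_weight("99", "right")

    def test_left_dominance_is_config_only(self):
        with pytest.raises(LookupError, match="left"):
            syntax_segment_weight("4", "left")

    def test_user_csv_overlays_the_default(self, tmp_path):
        path = tmp_path / "weights.csv"
        path.write_text("segment,dominance,weight\n4,left,1\n15,left,1\n")
        table = SyntaxWeightTable.from_csv(path, base=SyntaxWeightTable.default())
        assert table.lookup("4", "left").provenance == "user"
        assert table.lookup("6", "right").weight == Fraction(7, 2)

    def test_nonpositive_weight_rejected(self, tmp_path):
        path = tmp_path / "weights.csv"
        path.write_text("segment,dominance,weight\n4,left,0\n")
        with pytest.raises(ConfigurationError):
            SyntaxWeightTable.from_csv(path)


class TestLesionScore:
    def test_proximal_lad_occlusion_is_17_5(self):
        score = syntax_lesion_score(
            _lesion("6", occlusion=OcclusionClass.CHRONIC_TOTAL),
            lesion_only=True)
        assert score.value == Fraction(35, 2)

    def test_same_lesion_at_60pct_is_7(self):
        assert syntax_lesion_score(_lesion("6"), lesion_only=True).value == 7

    def test_posterolateral_branch_at_70pct_is_1(self):
        score = syntax_lesion_score(_lesion("16a", stenosis=70.0),
                                    lesion_only=True)
        assert score.value == 1

    def test_flags_without_points_config_is_explicit_error(self):
        lesion = _lesion("6", flags=AdverseFlags(thrombus=True))
        with pytest.raises(ConfigurationError, match="adverse"):
            syntax_lesion_score(lesion)
        # and no silent zeros: lesion_only must be asked for explicitly
        assert syntax_lesion_score(lesion, lesion_only=True).adverse_component == 0

    def test_adverse_points_reported_separately(self):
        lesion = _lesion("6", flags=AdverseFlags(thrombus=True,
                                                 heavy_calcification=True))
        score = syntax_lesion_score(lesion, adverse_points=DEFAULT_ADVERSE_POINTS)
        assert score.lesion_component == 7
        assert score.adverse_component == \
            DEFAULT_ADVERSE_POINTS["thrombus"] + \
            DEFAULT_ADVERSE_POINTS["heavy_calcification"]
        assert score.value == score.lesion_component + score.adverse_component

    def test_ineligible_lesion_is_contract_error(self):
        with pytest.raises(ContractError):
            syntax_lesion_score(_lesion("6", stenosis=30.0), lesion_only=True)

    def test_bilinear_in_weight_with_adverse_zeroed(self):
        """Doubling a segment weight doubles that lesion's contribution."""
        base = SyntaxWeightTable.default()
        doubled = SyntaxWeightTable(
            [type(e)(e.segment, e.dominance, e.weight * 2, e.provenance, e.name)
             for e in base.entries()]
        )
        for occ in (OcclusionClass.NONE, OcclusionClass.ACUTE_TOTAL):
            one = syntax_lesion_score(_lesion("7", occlusion=occ), base,
                                      lesion_only=True)
            two = syntax_lesion_score(_lesion("7", occlusion=occ), doubled,
                                      lesion_only=True)
            assert two.value == 2 * one.value


class TestAdaptedModification:
    def test_worked_case_12_5(self, figure2_tree):
        report = syntax_total(figure2_tree, modification=True, lesion_only=True)
        assert report.total == Fraction(25, 2)

    def test_no_preceding_branch_unchanged_17_5(self, figure2_tree):
        report = syntax_total(figure2_tree, modification=False, lesion_only=True)
        assert report.total == Fraction(35, 2)

    def test_two_branches_subtract_linearly(self):
        score = syntax_lesion_score(
            _lesion("6", occlusion=OcclusionClass.CHRONIC_TOTAL),
            lesion_only=True)
        modified = syntax_adapted_modification(score, [Fraction(1), Fraction(1)])
        assert modified.value == Fraction(15, 2)  # 17.5 - 10.0

    def test_empty_branch_list_is_identity(self):
        score = syntax_lesion_score(_lesion("6"), lesion_only=True)
        assert syntax_adapted_modification(score, []) == score

    def test_oversubtraction_clamps_with_warning(self):
        score = syntax_lesion_score(_lesion("16a", stenosis=70.0),
                                    lesion_only=True)
        modified = syntax_adapted_modification(score, [Fraction(4)])
        assert modified.value == 0
        assert any("clamped" in w for w in modified.warnings)


class TestTertiles:
    @pytest.mark.parametrize("score, tier", [
        (0, "low"), (22, "low"), (22.9, "low"), (23, "intermediate"),
        (30, "intermediate"), (32.9, "intermediate"), (33, "high"), (60, "high"),
    ])
    def test_boundaries_as_printed(self, score, tier):
        assert syntax_tertile(score) == tier

    def test_negative_score_is_domain_error(self):
        with pytest.raises(ValueError):
            syntax_tertile(-0.5)

    @settings(derandomize=True, max_examples=200)
    @given(score=st.floats(0, 100, allow_nan=False))
    def test_tier_functions_partition_the_half_line(self, score):
        assert syntax_tertile(score) in {"low", "intermediate", "high"}
        assert catlet_risk_tier(score) in {"low", "intermediate", "high"}


def _rca_table1_topology():
    """The full RCA system as tabulated: prox -> mid -> distal -> PDA + PLVs."""
    tree = CoronaryTree()
    tree.add_vessel(VesselNode("1", "RCA proximal", None))
    tree.add_vessel(VesselNode("2", "RCA mid", "1"))
    tree.add_vessel(VesselNode("3", "RCA distal", "2"))
    for seg in ("4", "16", "16a", "16b", "16c"):
        tree.add_vessel(VesselNode(seg, parent="3"))
    return tree


class TestConservationAudit:
    def test_syntax_table_violates_at_the_rca_node(self):
        tree = _rca_table1_topology()
        findings = flow_conservation_audit(syntax_weight_map(tree), tree)
        flagged = {f.node_id: f for f in findings}
        assert "3" in flagged  # parent 1.0 vs PDA 1.0 + four PLVs at 0.5
        assert flagged["3"].parent_weight == 1
        assert flagged["3"].daughters_weight == 3

    def test_three_plv_subbranches_sum_to_1_5(self):
        total = sum(
            syntax_segment_weight(seg, "right").weight
            for seg in ("16a", "16b", "16c")
        )
        assert total == Fraction(3, 2)

    def test_catlet_weights_conserve_on_the_same_topology(self):
        tree = _rca_table1_topology()
        for seg, count in [("4", 2), ("16", 1), ("16a", 1), ("16b", 1),
                           ("16c", 1)]:
            tree.vessels[seg].segments_supplied = Fraction(count)
        tree.add_vessel(VesselNode("left", "Left system", None,
                                   segments_supplied=11))
        assert flow_conservation_audit(derive_vessel_weights(tree), tree) == []

    def test_catlet_weights_conserve_for_all_54_patterns(self):
        for pattern in enumerate_patterns():
            tree = build_skeleton(pattern)
            weights = derive_vessel_weights(tree)
            assert flow_conservation_audit(weights, tree) == []

    def test_syntax_table_flags_at_least_one_node_on_the_skeleton(self):
        pattern = enumerate_patterns()[0]
        tree = build_skeleton(pattern)
        findings = flow_conservation_audit(syntax_weight_map(tree), tree)
        assert findings  # nomenclature-based weights cannot conserve flow
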