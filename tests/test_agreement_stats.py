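"""Agreement statistics against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from catlet import (
    category_free_nri,
    kappa_label,
    reclassification_table,
    weighted_kappa,
)

# ---------------------------------------------------------------------------
# Independent oracles: plain double-loop summations, written before and kept
# separate from the vectorised implementation they check.
# ---------------------------------------------------------------------------


def oracle_weighted_kappa(a, b, scheme):
    cats = sorted(set(a) | set(b))
    k = len(cats)
    idx = {c: i for i, c in enumerate(cats)}
    n = len(a)

    def weight(i, j):
        if scheme == "none":
            return 0.0 if i == j else 1.0
        if scheme == "linear":
            return abs(i - j) / (k - 1)
        return (abs(i - j) / (k - 1)) ** 2

    table = [[0] * k for _ in range(k)]
    for x, y in zip(a, b):
        table[idx[x]][idx[y]] += 1
    row = [sum(table[i][j] for j in range(k)) / n for i in range(k)]
    col = [sum(table[i][j] for i in range(k)) / n for j in range(k)]
    d_obs = sum(weight(i, j) * table[i][j] / n
                for i in range(k) for j in range(k))
    d_exp = sum(weight(i, j) * row[i] * col[j]
                for i in range(k) for j in range(k))
    return 1.0 - d_obs / d_exp


def oracle_nri(old, new, outcomes):
    up_e = down_e = up_ne = down_ne = n_e = n_ne = 0
    for o, nw, y in zip(old, new, outcomes):
        if y == 1:
            n_e += 1
            up_e += nw > o
            down_e += nw < o
        else:
            n_ne += 1
            up_ne += nw > o
            down_ne += nw < o
    return (up_e - down_e) / n_e + (down_ne - up_ne) / n_ne


class TestWeightedKappa:
    @pytest.mark.parametrize("scheme", ["none", "linear", "quadratic"])
    def test_matches_direct_formula_oracle(self, kappa_fixture, scheme):
        a, b = kappa_fixture
        result = weighted_kappa(a, b, scheme)
        assert result.kappa == pytest.approx(oracle_weighted_kappa(a, b, scheme),
                                             abs=1e-12)

    @pytest.mark.parametrize("scheme, sk_weights",
                             [("none", None), ("linear", "linear"),
                              ("quadratic", "quadratic")])
    def test_matches_sklearn_cross_check(self, kappa_fixture, scheme, sk_weights):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        a, b = kappa_fixture
        expected = sklearn_metrics.cohen_kappa_score(a, b, weights=sk_weights)
        assert weighted_kappa(a, b, scheme).kappa == pytest.approx(expected,
                                                                   abs=1e-12)

    def test_identical_ratings_give_kappa_1(self):
        result = weighted_kappa([1, 2, 3, 1, 2], [1, 2, 3, 1, 2])
        assert result.kappa == 1.0
        assert result.label == "almost perfect"

    def test_total_symmetric_disagreement_gives_minus_1(self):
        assert weighted_kappa([1, 1, 2, 2], [2, 2, 1, 1], "none").kappa == -1.0

    def test_constant_identical_raters_defined_as_1_with_warning(self):
        result = weighted_kappa([2, 2, 2], [2, 2, 2])
        assert result.kappa == 1.0
        assert result.warnings

    def test_mismatched_lengths_is_contract_error(self):
        with pytest.raises(ValueError, match="length"):
            weighted_kappa([1, 2], [1, 2, 3])

    def test_schemes_coincide_on_two_categories(self, kappa_fixture):
        """With k = 2 the three weighting schemes are identical by definition."""
        a = [x % 2 for x in kappa_fixture[0]]
        b = [x % 2 for x in kappa_fixture[1]]
        values = {s: weighted_kappa(a, b, s).kappa
                  for s in ("none", "linear", "quadratic")}
        assert values["none"] == values["linear"] == values["quadratic"]

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)),
                    min_size=2, max_size=40))
    def test_symmetric_in_raters(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        cats = list(range(4))
        ab = weighted_kappa(a, b, categories=cats).kappa
        ba = weighted_kappa(b, a, categories=cats).kappa
        assert ab == pytest.approx(ba, abs=1e-12)

    def test_bootstrap_ci_brackets_the_estimate_and_is_seeded(self, kappa_fixture):
        a, b = kappa_fixture
        r1 = weighted_kappa(a, b, bootstrap=200, rng=5)
        r2 = weighted_kappa(a, b, bootstrap=200, rng=5)
        assert r1.ci == r2.ci
        assert r1.ci[0] <= r1.kappa <= r1.ci[1]


class TestKappaLabel:
    @pytest.mark.parametrize("kappa, label", [
        (0.45, "moderate"),
        (0.85, "almost perfect"),
        (0.2, "fair"),            # shared boundary goes to the upper band
        (0.6, "substantial"),
        (0.05, "slight"),
        (1.0, "almost perfect"),
        (-0.3, "poor (below chance)"),
    ])
    def test_scale(self, kappa, label):
        assert kappa_label(kappa) == label

    def test_out_of_range_is_domain_error(self):
        with pytest.raises(ValueError):
            kappa_label(1.5)


class TestCategoryFreeNri:
    def test_matches_counting_oracle(self, nri_fixture):
        old, new, outcomes = nri_fixture
        result = category_free_nri(old, new, outcomes)
        assert result.nri == pytest.approx(oracle_nri(old, new, outcomes),
                                           abs=1e-12)
        # the fixture enumerates to 4 up / 2 down events, 2 up / 2 down nonevents
        assert (result.up_event, result.down_event) == (4, 2)
        assert (result.up_nonevent, result.down_nonevent) == (2, 2)

    def test_identical_scores_give_zero(self):
        result = category_free_nri([1, 2, 3, 4], [1, 2, 3, 4], [1, 0, 1, 0])
        assert result.nri == 0.0 and result.z == 0.0 and result.p_value == 1.0

    def test_maximal_improvement_is_2(self):
        result = category_free_nri([5, 5, 5, 5], [9, 1, 9, 1], [1, 0, 1, 0])
        assert result.nri == 2.0

    def test_antisymmetric_under_score_swap(self, nri_fixture):
        old, new, outcomes = nri_fixture
        forward = category_free_nri(old, new, outcomes)
        backward = category_free_nri(new, old, outcomes)
        assert forward.nri == pytest.approx(-backward.nri, abs=1e-12)

    @pytest.mark.parametrize("outcomes, group", [
        ([0, 0, 0], "events"), ([1, 1, 1], "nonevents"),
    ])
    def test_empty_outcome_group_names_it(self, outcomes, group):
        with pytest.raises(ValueError, match=group.rstrip("s")):
            category_free_nri([1, 2, 3], [3, 2, 1], outcomes)

    def test_z_has_the_large_sample_form(self, nri_fixture):
        old, new, outcomes = nri_fixture
        result = category_free_nri(old, new, outcomes)
        net_e = (4 - 2) / 6
        net_ne = (2 - 2) / 6
        var = ((4 + 2) / 6 - net_e ** 2) / 6 + ((2 + 2) / 6 - net_ne ** 2) / 6
        assert result.z == pytest.approx((net_e + net_ne) / math.sqrt(var),
                                         abs=1e-12)


class TestReclassificationTable:
    def test_identical_tiers_reclassify_nobody(self):
        tiers = ["low", "high", "intermediate", "low"]
        result = reclassification_table(tiers, tiers, [1, 0, 1, 0])
        assert result.pct_correct_events == 0.0
        assert result.pct_correct_nonevents == 0.0
        assert np.trace(result.events_table) == 2
        assert np.trace(result.nonevents_table) == 2

    def test_one_event_up_of_ten_is_10pct(self):
        old = ["low"] * 10
        new = ["intermediate"] + ["low"] * 9
        result = reclassification_table(old, new, [1] * 10)
        assert result.pct_correct_events == pytest.approx(10.0)

    def test_matches_cell_counting_oracle(self, reclass_fixture):
        old, new, outcomes = reclass_fixture
        order = {"low": 0, "intermediate": 1, "high": 2}
        up_e = sum(1 for o, nw, y in zip(old, new, outcomes)
                   if y == 1 and order[nw] > order[o])
        down_ne = sum(1 for o, nw, y in zip(old, new, outcomes)
                      if y == 0 and order[nw] < order[o])
        n_e = sum(outcomes)
        n_ne = len(outcomes) - n_e
        result = reclassification_table(old, new, outcomes)
        assert result.pct_correct_events == pytest.approx(100.0 * up_e / n_e,
                                                          abs=1e-12)
        assert result.pct_correct_nonevents == pytest.approx(
            100.0 * down_ne / n_ne, abs=1e-12)
        assert int(result.events_table.sum()) == n_e
        assert int(result.nonevents_table.sum()) == n_ne

    def test_unknown_tier_label_is_enumeration_error(self):
        with pytest.raises(ValueError, match="middling"):
            reclassification_table(["low"], ["middling"], [1])
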