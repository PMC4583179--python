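"""Membership functions, rule firing, and centroid defuzzification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fuzzedge.fuzzy_core import (
    FuzzyRule,
    FuzzySet,
    GaussianMF,
    OutputUniverse,
    TrapezoidalMF,
    defuzzify,
    firing_strength,
    infer_and_defuzzify,
)
from fuzzedge.detector import default_input_sets, default_output_sets, default_rules

from conftest import dense_centroid

LOWER = TrapezoidalMF(0, 0, 25, 75)
HIGHER = TrapezoidalMF(25, 75, 255, 255)


class TestMembershipClosedForms:
    @pytest.mark.parametrize(
        "mf, w, expected",
        [
            (LOWER, 0.0, 1.0),          # plateau of the Lower set
            (LOWER, 25.0, 1.0),         # plateau right edge
            (LOWER, 50.0, 0.5),         # midpoint of the falling ramp 25->75
            (LOWER, 75.0, 0.0),
            (LOWER, 200.0, 0.0),
            (HIGHER, 25.0, 0.0),        # foot of the rising ramp
            (HIGHER, 50.0, 0.5),
            (HIGHER, 75.0, 1.0),
            (HIGHER, 255.0, 1.0),       # plateau value at full contrast
            (GaussianMF(245, 3.5), 245.0, 1.0),
            (GaussianMF(245, 3.5), 248.5, np.exp(-0.5)),  # one width from centre
            (GaussianMF(10, 3.5), 10.0, 1.0),
        ],
    )
    def test_hand_values(self, mf, w, expected):
        assert mf(w) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_plateaus_no_division_by_zero(self):
        step_left = TrapezoidalMF(10, 10, 20, 30)   # r == s
        step_right = TrapezoidalMF(0, 10, 20, 20)   # t == u
        spike = TrapezoidalMF(5, 5, 5, 5)           # single point
        assert step_left(10) == 1.0
        assert step_left(9.999) == 0.0
        assert step_right(20) == 1.0
        assert step_right(20.001) == 0.0
        assert spike(5) == 1.0
        assert spike(4) == 0.0 and spike(6) == 0.0

    def test_invalid_parameters_rejected_at_construction(self):
        with pytest.raises(ValueError):
            TrapezoidalMF(10, 5, 20, 30)
        with pytest.raises(ValueError):
            GaussianMF(100, 0.0)
        with pytest.raises(ValueError):
            GaussianMF(100, -2.0)

    @given(
        breaks=st.lists(
            st.floats(-1000, 1000, allow_nan=False), min_size=4, max_size=4
        ).map(sorted),
        w=st.floats(-1000, 1000, allow_nan=False),
    )
    def test_trapezoid_bounded(self, breaks, w):
        mf = TrapezoidalMF(*breaks)
        assert 0.0 <= mf(w) <= 1.0

    @given(
        m=st.floats(-1000, 1000, allow_nan=False),
        d=st.floats(0.1, 500, allow_nan=False),
        w=st.floats(-1000, 1000, allow_nan=False),
    )
    def test_gaussian_bounded_and_positive(self, m, d, w):
        mf = GaussianMF(m, d)
        assert 0.0 < mf(w) <= 1.0 or mf(w) == 0.0  # underflow to 0 allowed
        assert mf(m) == 1.0

    def test_fuzzy_set_clamps_outside_universe(self):
        fset = FuzzySet("Higher", HIGHER)
        assert fset(300.0) == fset(255.0) == 1.0
        assert fset(-40.0) == fset(0.0) == 0.0


class TestRules:
    def test_rule_validation(self):
        with pytest.raises(ValueError):
            FuzzyRule({}, "Edge")
        with pytest.raises(ValueError):
            FuzzyRule({0: "Higher"}, "Edge")
        with pytest.raises(ValueError):
            FuzzyRule({9: "Higher"}, "Edge")

    def test_rule_text_roundtrip(self):
        rule = FuzzyRule.from_text("1:H 2:H 8:L => Edge")
        assert rule == FuzzyRule({1: "Higher", 2: "Higher", 8: "Lower"}, "Edge")

    def test_firing_strength_examples(self):
        sets = default_input_sets()
        rule1 = default_rules()[0]  # dP1 Higher, dP2 Higher, dP8 Lower
        deltas = np.zeros(8)
        deltas[0] = deltas[1] = 255.0
        assert firing_strength(rule1, deltas, sets) == 1.0
        # one antecedent at membership 0 kills the rule
        deltas2 = deltas.copy()
        deltas2[7] = 255.0  # Lower(255) = 0
        assert firing_strength(rule1, deltas2, sets) == 0.0
        # min over partial memberships
        deltas3 = deltas.copy()
        deltas3[0] = 50.0  # Higher(50) = 0.5
        assert firing_strength(rule1, deltas3, sets) == pytest.approx(0.5)

    def test_dont_care_inputs_do_not_participate(self, rng):
        sets = default_input_sets()
        rule1 = default_rules()[0]
        base = np.zeros(8)
        base[0] = base[1] = 255.0
        for _ in range(10):
            varied = base.copy()
            for j in (2, 3, 4, 5, 6):  # don't-care indices of rule 1
                varied[j] = rng.uniform(0, 255)
            assert firing_strength(rule1, varied, sets) == 1.0

    def test_higher_antecedent_monotone(self, rng):
        """Strength is non-decreasing in a Higher delta, non-increasing in a
        Lower delta (ramp directions of the input sets)."""
        sets = default_input_sets()
        rule = default_rules()[0]
        for _ in range(50):
            deltas = rng.uniform(0, 255, 8)
            s0 = firing_strength(rule, deltas, sets)
            up = deltas.copy()
            up[0] = min(255.0, up[0] + rng.uniform(0, 80))
            assert firing_strength(rule, up, sets) >= s0 - 1e-12
            worse = deltas.copy()
            worse[7] = min(255.0, worse[7] + rng.uniform(0, 80))
            assert firing_strength(rule, worse, sets) <= s0 + 1e-12


class TestDefuzzify:
    def test_pure_consequents_hit_output_centres(self):
        out = default_output_sets()
        uni = OutputUniverse()
        c_edge = defuzzify({"Edge": 1.0, "NonEdge": 0.0}, out, uni)
        c_non = defuzzify({"Edge": 0.0, "NonEdge": 1.0}, out, uni)
        # truncation of the Gaussians to [0,255] shifts the centroid slightly
        assert abs(c_edge - 245.0) < 1.0
        assert abs(c_non - 10.0) < 1.0

    def test_balanced_strengths_land_mid_grey(self):
        out = default_output_sets()
        uni = OutputUniverse()
        c = defuzzify({"Edge": 0.5, "NonEdge": 0.5}, out, uni)
        # output Gaussians share d and sit symmetrically (10 and 245 = 255-10)
        assert c == pytest.approx(127.5, abs=0.5)

    def test_all_zero_aggregate_uses_fallback(self):
        out = default_output_sets()
        uni = OutputUniverse()
        assert defuzzify({"Edge": 0.0, "NonEdge": 0.0}, out, uni, fallback=10.0) == 10.0
        with pytest.raises(ValueError):
            defuzzify({"Edge": 0.0, "NonEdge": 0.0}, out, uni)

    def test_agrees_with_dense_brute_force_oracle(self, rng):
        """100 random strength profiles vs a 10x denser independent centroid."""
        out = default_output_sets()
        uni = OutputUniverse(n=256)
        for _ in range(100):
            e, ne = rng.uniform(0.001, 1.0, 2)
            c = defuzzify({"Edge": e, "NonEdge": ne}, out, uni)
            oracle = dense_centroid({"Edge": e, "NonEdge": ne}, out, n=2560)
            assert abs(c - oracle) < 0.5

    def test_monotone_in_edge_strength(self):
        out = default_output_sets()
        uni = OutputUniverse()
        for ne in (0.2, 0.5, 0.9):
            scores = [
                defuzzify({"Edge": e, "NonEdge": ne}, out, uni)
                for e in np.linspace(0.0, 1.0, 21)
            ]
            assert all(b >= a - 1e-9 for a, b in zip(scores, scores[1:]))

    def test_infer_and_defuzzify_aggregates_by_max(self):
        out = default_output_sets()
        uni = OutputUniverse()
        rules = default_rules()[:3]
        strengths = [0.2, 0.7, 0.4]  # all Edge rules -> aggregate 0.7
        c = infer_and_defuzzify(rules, strengths, out, uni, fallback=10.0)
        assert c == pytest.approx(defuzzify({"Edge": 0.7}, out, uni), abs=1e-9)

    def test_universe_validation(self):
        with pytest.raises(ValueError):
            OutputUniverse(n=1)
        uni = OutputUniverse(0, 255, 256)
        assert uni.points[0] == 0.0 and uni.points[-1] == 255.0
        assert np.allclose(np.diff(uni.points), np.diff(uni.points)[0])
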