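"""Coordination model: deviation, coordination, composite, development."""

import math

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import riverhealth as rh
from riverhealth.cdd import (
    assess_functions,
    assess_unit,
    composite_index,
    coordinated_development,
    coordination_degree,
    deviation_coefficient,
    relative_development,
    subsystem_index,
)

fg = st.floats(0.01, 1.0)


def _dev_oracle(f, g):
    return math.sqrt(max(0.0, 1.0 - f * g / ((f + g) / 2.0) ** 2))


class TestDeviationAndCoordination:
    def test_equal_subsystems_have_zero_deviation(self):
        assert deviation_coefficient(0.5, 0.5) == 0.0
        assert coordination_degree(0.5, 0.5) == 1.0

    def test_total_divergence(self):
        assert deviation_coefficient(1.0, 0.0) == pytest.approx(1.0)
        assert coordination_degree(1.0, 0.0) == pytest.approx(0.0)

    def test_direct_substitution(self):
        # whole-river upstream values: f = 0.664, g = f / 0.954
        f, g = 0.664, 0.664 / 0.954
        assert deviation_coefficient(f, g) == pytest.approx(_dev_oracle(f, g), abs=1e-12)
        assert deviation_coefficient(0.664, 0.696) == pytest.approx(0.0237, abs=5e-4)
        assert coordination_degree(0.664, 0.696) == pytest.approx(0.99944, abs=5e-5)

    def test_undefined_for_both_zero(self):
        with pytest.raises(ValueError):
            deviation_coefficient(0.0, 0.0)

    @given(f=fg, g=fg)
    def test_algebraic_identity(self, f, g):
        """C computed as 1 - C_fg^2 equals f*g/((f+g)/2)^2 to 1e-12."""
        direct = f * g / ((f + g) / 2.0) ** 2
        assert coordination_degree(f, g) == pytest.approx(direct, abs=1e-12)

    @given(f=fg, g=fg)
    def test_symmetry(self, f, g):
        assert coordination_degree(f, g) == pytest.approx(
            coordination_degree(g, f), abs=1e-15
        )
        assert 0.0 <= coordination_degree(f, g) <= 1.0


class TestCompositeIndex:
    def test_constant_case(self):
        assert composite_index(0.5, 0.5, 0.67, 0.33) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "f, g, expected",
        [
            (0.64625, 0.625, 0.639),   # f = g*E with printed 2011 g, E
            (0.652925, 0.637, 0.648),  # 2012
        ],
    )
    def test_published_composites(self, f, g, expected):
        assert composite_index(f, g, 0.67, 0.33) == pytest.approx(expected, abs=5e-4)

    def test_weights_must_partition_one(self):
        with pytest.raises(ValueError):
            composite_index(0.5, 0.5, 0.67, 0.43)

    @given(f=fg, g=fg)
    def test_bounded_by_subsystems(self, f, g):
        t = composite_index(f, g, 0.67, 0.33)
        assert min(f, g) - 1e-12 <= t <= max(f, g) + 1e-12


class TestDevelopmentDegrees:
    def test_geometric_mean_of_balance_and_level(self):
        assert coordinated_development(1.0, 0.639) == pytest.approx(0.799, abs=5e-4)
        assert coordinated_development(0.0, 0.9) == 0.0
        assert coordinated_development(1.0, 1.0) == 1.0

    def test_relative_development(self):
        assert relative_development(0.5, 0.5) == 1.0
        assert relative_development(0.664, 0.69601) == pytest.approx(0.954, abs=5e-4)
        assert relative_development(0.65565, 0.705) == pytest.approx(0.930, abs=5e-4)
        with pytest.raises(ValueError):
            relative_development(0.5, 0.0)

    @given(f=fg, g=fg)
    def test_relative_reciprocal(self, f, g):
        assert relative_development(f, g) == pytest.approx(
            1.0 / relative_development(g, f), rel=1e-12
        )

    @given(c1=st.floats(0, 1), c2=st.floats(0, 1), t=st.floats(0, 1))
    def test_monotone_in_coordination_and_level(self, c1, c2, t):
        lo, hi = sorted((c1, c2))
        assert coordinated_development(lo, t) <= coordinated_development(hi, t) + 1e-12
        assert coordinated_development(t, lo) <= coordinated_development(t, hi) + 1e-12


class TestAssessment:
    def test_perfect_river(self):
        r = assess_functions(1.0, 1.0, 0.67, 0.33)
        assert (r.f_natural, r.g_social) == (1.0, 1.0)
        assert r.deviation == 0.0
        assert r.coordination == 1.0
        assert r.composite == 1.0
        assert r.development == 1.0
        assert r.relative == 1.0

    @given(f=fg, g=fg)
    def test_chain_matches_step_by_step_oracle(self, f, g):
        r = assess_functions(f, g, 0.67, 0.33)
        c_fg = _dev_oracle(f, g)
        c = 1.0 - c_fg**2
        t = 0.67 * f + 0.33 * g
        assert r.deviation == pytest.approx(c_fg, abs=1e-12)
        assert r.development == pytest.approx(math.sqrt(c * t), abs=1e-12)
        assert r.relative == pytest.approx(f / g, rel=1e-12)

    @given(s=fg)
    def test_balanced_closed_form(self, s):
        """When f = g = s: C = 1, T = s, D = sqrt(s), E = 1."""
        r = assess_functions(s, s, 0.67, 0.33)
        assert r.coordination == 1.0
        assert r.composite == pytest.approx(s, abs=1e-12)
        assert r.development == pytest.approx(math.sqrt(s), abs=1e-12)
        assert r.relative == 1.0

    def test_upstream_station_development(self, fixture_bundle):
        f = fixture_bundle.f_spatial["upstream"]
        e = fixture_bundle.E_spatial["upstream"]
        r = assess_functions(f, f / e, 0.67, 0.33)
        assert r.development == pytest.approx(0.821, abs=5e-3)

    def test_assess_unit_composes_subsystem_indices(self, registry, default_panel):
        _, observations, _ = default_panel
        matrix = rh.build_score_matrix(observations, registry)
        weights = rh.entropy_weights(matrix, registry)
        unit = matrix.index[0]
        scores = matrix.loc[unit].to_dict()
        r = assess_unit(scores, weights, unit=str(unit))
        # independent dot-product oracle for the subsystem indices
        f = sum(weights.weights[i] * scores[i] for i in weights.natural)
        f /= sum(weights.weights[i] for i in weights.natural)
        g = sum(weights.weights[i] * scores[i] for i in weights.social)
        g /= sum(weights.weights[i] for i in weights.social)
        assert r.f_natural == pytest.approx(f, abs=1e-12)
        assert r.g_social == pytest.approx(g, abs=1e-12)
        assert r.development == pytest.approx(
            math.sqrt((1 - _dev_oracle(f, g) ** 2)
                      * (weights.w_natural * f + weights.w_social * g)),
            abs=1e-12,
        )


class TestSubsystemIndex:
    def test_constant_scores_give_constant_index(self, registry, default_panel):
        _, observations, _ = default_panel
        matrix = rh.build_score_matrix(observations, registry)
        weights = rh.entropy_weights(matrix, registry)
        scores = {i: 0.63 for i in registry.indicator_ids}
        assert subsystem_index(scores, weights, "natural") == pytest.approx(0.63)
        assert subsystem_index(scores, weights, "social") == pytest.approx(0.63)

    def test_missing_indicator_rejected(self, registry, default_panel):
        _, observations, _ = default_panel
        matrix = rh.build_score_matrix(observations, registry)
        weights = rh.entropy_weights(matrix, registry)
        scores = {i: 0.5 for i in registry.indicator_ids if i != "C4"}
        with pytest.raises(KeyError, match="C4"):
            subsystem_index(scores, weights, "natural")
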