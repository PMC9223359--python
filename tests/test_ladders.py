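"""Threshold-ladder scoring: interpolation, clamps, monotonicity, inversion."""

import math

import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from riverhealth import LadderError, ParabolicRule, ThresholdLadder
from riverhealth.ladders import score_composite_mean, score_composite_min

FLOOD_LADDER = ThresholdLadder(
    "C11", "benefit", {1.0: 0.95, 0.8: 0.90, 0.6: 0.85, 0.4: 0.80, 0.2: 0.70, 0.0: 0.50}
)
FLOW_DEV_LADDER = ThresholdLadder(
    "C1", "cost", {1.0: 0.05, 0.8: 0.1, 0.6: 0.3, 0.4: 0.8, 0.2: 2.0, 0.0: 5.0}
)


@pytest.mark.parametrize(
    "ladder, value, expected",
    [
        (FLOOD_LADDER, 0.95, 1.0),  # at/above the optimum
        (FLOOD_LADDER, 0.99, 1.0),
        (FLOOD_LADDER, 0.50, 0.0),  # bottom-threshold clamp
        (FLOOD_LADDER, 0.30, 0.0),
        # two-point interpolation oracle: 0.8 + 0.2*(92.5-90)/(95-90) = 0.9
        (FLOOD_LADDER, 0.925, 0.9),
        (FLOW_DEV_LADDER, 5.0, 0.0),  # worst threshold of a cost ladder
        (FLOW_DEV_LADDER, 7.0, 0.0),
        (FLOW_DEV_LADDER, 0.05, 1.0),
        (FLOW_DEV_LADDER, 0.02, 1.0),
        # cost interpolation: 0.6 + 0.2*(0.3-0.2)/(0.3-0.1) = 0.7
        (FLOW_DEV_LADDER, 0.2, 0.7),
    ],
)
def test_ladder_scores(ladder, value, expected):
    assert ladder.score(value) == pytest.approx(expected, abs=1e-12)


def test_anchor_exactness():
    """A value exactly at a defined threshold returns exactly that anchor score."""
    for ladder in (FLOOD_LADDER, FLOW_DEV_LADDER):
        for score, threshold in ladder.anchors:
            assert ladder.score(threshold) == score


def test_step_ladder_optimistic_tie_break():
    """Equal adjacent thresholds act as a step; the shared value takes the
    higher score."""
    step = ThresholdLadder(
        "EF1", "benefit", {1.0: 0.50, 0.8: 0.40, 0.4: 0.30, 0.2: 0.10, 0.0: 0.10}
    )
    assert step.score(0.10) == 0.2
    assert step.score(0.09) == 0.0
    assert step.score(0.11) == pytest.approx(0.2 + 0.2 * 0.01 / 0.20)


@pytest.mark.parametrize(
    "anchors, orientation",
    [
        ({1.0: 0.0, 0.6: 0.25, 0.4: 0.5, 0.2: 0.2}, "cost"),  # reversal
        ({1.0: 1.0, 0.5: 2.0}, "benefit"),  # wrong direction
        ({1.0: 1.0}, "benefit"),  # single anchor
    ],
)
def test_invalid_ladders_rejected(anchors, orientation):
    with pytest.raises(LadderError):
        ThresholdLadder("bad", orientation, anchors)


def test_non_finite_value_rejected():
    with pytest.raises(ValueError):
        FLOOD_LADDER.score(float("nan"))


def test_anchor_order_is_canonical():
    shuffled = ThresholdLadder(
        "C11", "benefit", [(0.6, 0.85), (1.0, 0.95), (0.0, 0.50), (0.8, 0.90),
                           (0.4, 0.80), (0.2, 0.70)]
    )
    assert shuffled.anchors == FLOOD_LADDER.anchors


def _ladders():
    anchor_scores = st.lists(
        st.sampled_from([0.0, 0.2, 0.3, 0.4, 0.6, 0.8, 1.0]),
        min_size=2, max_size=7, unique=True,
    )
    thresholds = st.lists(
        st.floats(min_value=-100, max_value=100, allow_nan=False,
                  allow_infinity=False),
        min_size=7, max_size=7, unique=True,
    )
    orientation = st.sampled_from(["benefit", "cost"])

    @st.composite
    def build(draw):
        scores = sorted(draw(anchor_scores))
        ts = sorted(draw(thresholds))[: len(scores)]
        orient = draw(orientation)
        if orient == "cost":
            ts = ts[::-1]
        return ThresholdLadder("H", orient, list(zip(scores, ts)))

    return build()


@given(ladder=_ladders(), v1=st.floats(-150, 150), v2=st.floats(-150, 150))
def test_ladder_monotone(ladder, v1, v2):
    """Benefit ladders never score a larger value lower; cost ladders mirror."""
    lo, hi = sorted((v1, v2))
    s_lo, s_hi = ladder.score(lo), ladder.score(hi)
    if ladder.orientation == "benefit":
        assert s_lo <= s_hi + 1e-12
    else:
        assert s_hi <= s_lo + 1e-12
    assert 0.0 <= s_lo <= 1.0 and 0.0 <= s_hi <= 1.0


@given(ladder=_ladders(), target=st.floats(0, 1))
def test_ladder_round_trip(ladder, target):
    """Inverting any attainable target score and re-scoring recovers it."""
    snapped = ladder.attainable(target)
    value = ladder.invert(snapped)
    assert ladder.score(value) == pytest.approx(snapped, abs=1e-9)


class TestParabolicRule:
    rule = ParabolicRule()

    def test_zero_at_cutoff(self):
        assert self.rule.score(0.6) == 0.0
        assert self.rule.score(0.75) == 0.0

    def test_maximum_at_vertex(self):
        assert self.rule.vertex == pytest.approx(0.30, abs=1e-4)
        assert self.rule.score(0.30) == 1.0

    def test_zero_at_zero_utilization(self):
        assert self.rule.score(0.0) == 0.0

    def test_reasonable_band_scores_high(self):
        # a moderate utilization rate (30-40%) is the healthy optimum
        assert self.rule.score(0.35) > 0.9

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            self.rule.score(1.2)
        with pytest.raises(ValueError):
            self.rule.score(-0.1)

    def test_positive_quadratic_coefficient_rejected(self):
        with pytest.raises(LadderError):
            ParabolicRule(coef_a=1111.11)

    @given(target=st.floats(0, 1))
    def test_round_trip(self, target):
        rate = self.rule.invert(target)
        peak = self.rule.score(self.rule.vertex)
        expected = min(target, peak)
        assert self.rule.score(rate) == pytest.approx(expected, abs=1e-9)


class TestCompositeRules:
    def test_min_picks_worst_component(self):
        # e.g. DO vs nutrient vs metal scores: the nutrient score governs
        assert score_composite_min([0.98, 0.90, 0.93]) == 0.90
        assert score_composite_min([1.0, 1.0, 1.0]) == 1.0
        assert score_composite_min([0.2, 0.7]) == 0.2

    def test_mean_of_biology_scores(self):
        assert score_composite_mean([0.54, 0.71]) == pytest.approx(0.625)
        assert score_composite_mean([0.3, 0.3]) == pytest.approx(0.3)
        assert score_composite_mean([0.0, 1.0]) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            score_composite_min([])
        with pytest.raises(ValueError):
            score_composite_mean([])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_min_never_exceeds_mean(self, scores):
        assert score_composite_min(scores) <= score_composite_mean(scores) + 1e-12
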