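"""Piecewise-linear threshold ladders and the parabolic utilization rule.

A *threshold ladder* is the ordered set of (score anchor, raw threshold)
breakpoints used to rescale a raw indicator value onto a [0, 1] health
score.  Benefit-oriented indicators (larger raw value is healthier) use
thresholds that increase with the score anchors; cost-oriented indicators
(smaller is healthier, e.g. pollutant concentrations) use thresholds that
decrease.  Between adjacent anchors the score is linearly interpolated;
beyond the outermost anchors it is clamped to the outermost anchor scores.

Water-resource utilization is scored by a separate parabolic rule: the
score rises to a maximum at a moderate utilization rate and falls to zero
at an upper cutoff beyond which exploitation is considered unhealthy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence, Tuple

__all__ = [
    "LadderError",
    "ThresholdLadder",
    "ParabolicRule",
    "score_composite_min",
    "score_composite_mean",
]

#: Score anchors a ladder may use, in canonical order.
CANONICAL_ANCHORS = (0.0, 0.2, 0.3, 0.4, 0.6, 0.8, 1.0)

Orientation = Literal["benefit", "cost"]


class LadderError(ValueError):
    """Raised when a ladder or rule definition is internally inconsistent."""


def _check_finite(value: float, what: str) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{what} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ThresholdLadder:
    """Ordered (score anchor, raw threshold) breakpoints for one indicator.

    Parameters
    ----------
    indicator_id:
        Label of the indicator (or indicator component) the ladder scores.
    orientation:
        ``"benefit"`` if larger raw values earn higher scores, ``"cost"``
        if smaller raw values do.
    anchors:
        Mapping or iterable of ``(score, threshold)`` pairs.  Canonically
        re-sorted by score on construction, so input order is irrelevant.
        Equal thresholds on adjacent anchors encode a step; a value at the
        shared threshold takes the higher score (optimistic tie-break).

    Raises
    ------
    LadderError
        If fewer than two anchors are given, score anchors repeat, or the
        thresholds are not monotone in the direction the orientation
        implies.
    """

    indicator_id: str
    orientation: Orientation
    anchors: Tuple[Tuple[float, float], ...]
    notes: str = ""

    def __init__(
        self,
        indicator_id: str,
        orientation: Orientation,
        anchors: Mapping[float, float] | Iterable[Tuple[float, float]],
        notes: str = "",
    ) -> None:
        if isinstance(anchors, Mapping):
            pairs = [(float(s), float(t)) for s, t in anchors.items()]
        else:
            pairs = [(float(s), float(t)) for s, t in anchors]
        pairs.sort(key=lambda p: p[0])
        object.__setattr__(self, "indicator_id", str(indicator_id))
        object.__setattr__(self, "orientation", orientation)
        object.__setattr__(self, "anchors", tuple(pairs))
        object.__setattr__(self, "notes", notes)
        self._validate()

    def _validate(self) -> None:
        if self.orientation not in ("benefit", "cost"):
            raise LadderError(
                f"{self.indicator_id}: orientation must be 'benefit' or "
                f"'cost', got {self.orientation!r}"
            )
        if len(self.anchors) < 2:
            raise LadderError(
                f"{self.indicator_id}: at least two anchors are required "
                "for interpolation"
            )
        scores = [s for s, _ in self.anchors]
        thresholds = [t for _, t in self.anchors]
        for s, t in self.anchors:
            _check_finite(s, f"{self.indicator_id}: anchor score")
            _check_finite(t, f"{self.indicator_id}: anchor threshold")
            if not 0.0 <= s <= 1.0:
                raise LadderError(
                    f"{self.indicator_id}: anchor score {s} outside [0, 1]"
                )
        if any(b <= a for a, b in zip(scores, scores[1:])):
            raise LadderError(
                f"{self.indicator_id}: duplicate score anchors {scores}"
            )
        sign = 1.0 if self.orientation == "benefit" else -1.0
        for (s0, t0), (s1, t1) in zip(self.anchors, self.anchors[1:]):
            if sign * (t1 - t0) < 0.0:
                raise LadderError(
                    f"{self.indicator_id}: non-monotone ladder — threshold "
                    f"{t1} at score {s1} reverses against {t0} at score {s0} "
                    f"for {self.orientation} orientation"
                )

    # -- scoring -----------------------------------------------------------

    def score(self, value: float) -> float:
        """Score a raw value on this ladder.

        Returns the piecewise-linear interpolation between the bracketing
        anchors, clamped to the outermost anchor scores.  A value exactly
        at a threshold shared by several anchors (a step) takes the
        highest of their scores.
        """
        value = _check_finite(value, f"{self.indicator_id}: value")
        # exact-threshold hits return the anchor score exactly
        hits = [s for s, t in self.anchors if t == value]
        if hits:
            return max(hits)
        sign = 1.0 if self.orientation == "benefit" else -1.0
        v = sign * value
        pairs = [(s, sign * t) for s, t in self.anchors]  # t' ascending
        if v <= pairs[0][1]:
            return pairs[0][0]
        if v >= pairs[-1][1]:
            return pairs[-1][0]
        for (s0, t0), (s1, t1) in zip(pairs, pairs[1:]):
            if t0 < v <= t1:
                frac = (v - t0) / (t1 - t0)
                return min(1.0, max(0.0, s0 + frac * (s1 - s0)))
        raise AssertionError("unreachable: anchors cover the value range")

    # -- inversion ---------------------------------------------------------

    def attainable(self, target: float) -> float:
        """Snap a target score to the nearest score this ladder can emit."""
        target = _check_finite(target, "target score")
        scores = [s for s, _ in self.anchors]
        lo, hi = scores[0], scores[-1]
        snapped = min(max(target, lo), hi)
        # scores inside a step (equal adjacent thresholds) have no preimage
        for (s0, t0), (s1, t1) in zip(self.anchors, self.anchors[1:]):
            if t0 == t1 and s0 < snapped < s1:
                snapped = s0 if (snapped - s0) < (s1 - snapped) else s1
        return snapped

    def invert(self, target: float) -> float:
        """Return a raw value that scores to ``target``.

        The target must be attainable (see :meth:`attainable`); otherwise a
        warning is emitted and the nearest attainable score is inverted
        instead.  Where the ladder is flat (clamped tails), the outermost
        threshold itself is returned.
        """
        target = _check_finite(target, "target score")
        snapped = self.attainable(target)
        if snapped != target:
            warnings.warn(
                f"{self.indicator_id}: score {target:g} has no raw preimage; "
                f"using nearest attainable score {snapped:g}",
                stacklevel=2,
            )
        target = snapped
        for s, t in self.anchors:
            if s == target:
                return t
        for (s0, t0), (s1, t1) in zip(self.anchors, self.anchors[1:]):
            if s0 < target < s1:
                frac = (target - s0) / (s1 - s0)
                return t0 + frac * (t1 - t0)
        raise AssertionError("unreachable: snapped target is attainable")


@dataclass(frozen=True)
class ParabolicRule:
    """Parabolic score for the water-resource utilization rate.

    ``score = clip((coef_a * r**2 + coef_b * r) / scale, 0, 1)`` for a
    utilization rate ``r`` (fraction of available water resources consumed),
    and exactly 0 at or beyond ``cutoff``.  With the default coefficients
    the vertex sits at r = 0.30 (score 1): moderate utilization is
    healthiest, while both negligible and excessive exploitation score low.
    """

    coef_a: float = -1111.11
    coef_b: float = 666.67
    scale: float = 100.0
    cutoff: float = 0.6
    notes: str = ""

    def __post_init__(self) -> None:
        if self.coef_a >= 0:
            raise LadderError(
                "parabolic rule needs coef_a < 0 for an interior maximum"
            )
        vertex = self.vertex
        if not 0.0 < vertex < 1.0:
            raise LadderError(
                f"parabola vertex {vertex:.4f} must lie strictly inside (0, 1)"
            )
        if not 0.0 < self.cutoff <= 1.0:
            raise LadderError("cutoff must lie in (0, 1]")

    @property
    def vertex(self) -> float:
        """Utilization rate at which the score peaks."""
        return -self.coef_b / (2.0 * self.coef_a)

    def score(self, rate: float) -> float:
        """Score a utilization rate in [0, 1]."""
        rate = _check_finite(rate, "utilization rate")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(
                f"utilization rate must be a fraction in [0, 1], got {rate}"
            )
        if rate >= self.cutoff:
            return 0.0
        raw = (self.coef_a * rate * rate + self.coef_b * rate) / self.scale
        return min(1.0, max(0.0, raw))

    def invert(self, target: float) -> float:
        """Utilization rate on the ascending branch that scores ``target``.

        The preimage of 0 is taken as rate 0 (the ascending-branch root).
        Targets above the parabola's maximum snap down with a warning.
        """
        target = _check_finite(target, "target score")
        if not 0.0 <= target <= 1.0:
            raise ValueError(f"target score must lie in [0, 1], got {target}")
        if target == 0.0:
            return 0.0
        peak = self.score(self.vertex) if self.vertex < self.cutoff else 1.0
        if target > peak:
            warnings.warn(
                f"target score {target:g} exceeds the parabola maximum "
                f"{peak:g}; using the vertex rate",
                stacklevel=2,
            )
            return self.vertex
        disc = self.coef_b**2 + 4.0 * self.coef_a * target * self.scale
        if disc < 0.0:  # float fuzz at the very peak
            return self.vertex
        root = (-self.coef_b + math.sqrt(disc)) / (2.0 * self.coef_a)
        return root


def score_composite_min(component_scores: Sequence[float]) -> float:
    """Worst-component rule: the minimum of the component scores.

    Used where any single failing component (one metal, one nutrient, one
    flow period) compromises the indicator as a whole.
    """
    return _combine(component_scores, min)


def score_composite_mean(component_scores: Sequence[float]) -> float:
    """Arithmetic-mean rule for component or sampling-point scores."""
    scores = _validated(component_scores)
    return sum(scores) / len(scores)


def _combine(component_scores: Sequence[float], fn) -> float:
    return fn(_validated(component_scores))


def _validated(component_scores: Sequence[float]) -> list[float]:
    scores = [float(s) for s in component_scores]
    if not scores:
        raise ValueError("component score list must be non-empty")
    for s in scores:
        if not math.isfinite(s) or not 0.0 <= s <= 1.0:
            raise ValueError(f"component score {s} outside [0, 1]")
    return scores
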