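"""Grade classification of the assessment statistics.

The riverine state index T and the coordinated development degree D are
each mapped onto five uniform grades on [0, 1]; the relative development
degree E is mapped onto three grades around the synchronized band
[0.8, 1.2].  Bins are half-open [lower, upper) with the top bin closed at
1.0, so e.g. D = 0.8 already counts as highly coordinated; for E the
synchronized band is closed at both ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Tuple

__all__ = [
    "GradeScheme",
    "default_scheme",
    "grade_state",
    "grade_coordination",
    "grade_relative",
]

Bin = Tuple[float, float, str]

STATE_LABELS = ("Critical", "Poor", "Medium", "Good", "Excellent")
COORDINATION_LABELS = (
    "Severely uncoordinated development",
    "Moderately uncoordinated development",
    "Barely coordinated development",
    "Moderately coordinated development",
    "Highly coordinated development",
)
RELATIVE_LABELS = (
    "Slow development of the natural functions",
    "Synchronized development",
    "Slow development of the social functions",
)


def _uniform_bins(labels: Tuple[str, ...]) -> Tuple[Bin, ...]:
    n = len(labels)
    return tuple(
        (i / n, (i + 1) / n, label) for i, label in enumerate(labels)
    )


@dataclass(frozen=True)
class GradeScheme:
    """Classification bins for T, D and E.

    ``state_bins`` and ``coordination_bins`` must partition [0, 1] without
    gaps or overlaps; ``relative_thresholds`` are the (lower, upper) edges
    of the synchronized band for E.
    """

    state_bins: Tuple[Bin, ...] = field(default_factory=lambda: _uniform_bins(STATE_LABELS))
    coordination_bins: Tuple[Bin, ...] = field(
        default_factory=lambda: _uniform_bins(COORDINATION_LABELS)
    )
    relative_thresholds: Tuple[float, float] = (0.8, 1.2)
    relative_labels: Tuple[str, str, str] = RELATIVE_LABELS

    def __post_init__(self) -> None:
        for name, bins in (
            ("state_bins", self.state_bins),
            ("coordination_bins", self.coordination_bins),
        ):
            if not bins:
                raise ValueError(f"{name} must be non-empty")
            lo = bins[0][0]
            if lo != 0.0 or bins[-1][1] != 1.0:
                raise ValueError(f"{name} must span [0, 1]")
            cursor = 0.0
            for low, high, _label in bins:
                if low != cursor or high <= low:
                    raise ValueError(f"{name} has gaps or overlaps at {low}")
                cursor = high
        lo, hi = self.relative_thresholds
        if not 0.0 < lo < hi:
            raise ValueError("relative thresholds must satisfy 0 < lower < upper")


_DEFAULT = GradeScheme()


def default_scheme() -> GradeScheme:
    """The standard five-grade / three-grade classification."""
    return _DEFAULT


def _grade(value: float, bins: Tuple[Bin, ...], what: str) -> str:
    if not math.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ValueError(f"{what} must lie in [0, 1], got {value}")
    for low, high, label in bins:
        if low <= value < high:
            return label
    return bins[-1][2]  # value == 1.0 falls into the closed top bin


def grade_state(composite: float, scheme: GradeScheme | None = None) -> str:
    """Grade the riverine state index T (Critical … Excellent)."""
    scheme = scheme or _DEFAULT
    return _grade(composite, scheme.state_bins, "riverine state index")


def grade_coordination(development: float, scheme: GradeScheme | None = None) -> str:
    """Grade the coordinated development degree D."""
    scheme = scheme or _DEFAULT
    return _grade(development, scheme.coordination_bins, "coordinated development degree")


def grade_relative(relative: float, scheme: GradeScheme | None = None) -> str:
    """Grade the relative development degree E.

    E below the synchronized band means the natural functions lag; above it
    the social functions lag; inside (closed at both ends) development is
    synchronized.
    """
    scheme = scheme or _DEFAULT
    if not math.isfinite(relative) or relative <= 0.0:
        raise ValueError(f"relative development degree must be positive, got {relative}")
    lo, hi = scheme.relative_thresholds
    low_label, mid_label, high_label = scheme.relative_labels
    if relative < lo:
        return low_label
    if relative > hi:
        return high_label
    return mid_label
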