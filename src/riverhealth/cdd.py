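"""The coordinated development degree (CDD) model for one evaluation unit.

The model condenses the 16 indicator scores of a station-year into two
subsystem indices — natural functions f and social functions g — and then
measures both their *level* and their *balance*:

    f = Σ w_i s_i / W_natural          (weighted mean of natural scores)
    g = Σ w_j s_j / W_social           (weighted mean of social scores)
    C_fg = sqrt(1 - f·g / ((f+g)/2)²)  deviation coefficient
    C    = 1 - C_fg²                   coordination degree
    T    = W_natural·f + W_social·g    composite evaluation index
    D    = sqrt(C·T)                   coordinated development degree
    E    = f / g                       relative development degree

C is 1 exactly when f = g and decays as they diverge; T blends the two
levels with the subsystem entropy-weight sums; D rewards rivers that are
simultaneously healthy (high T) and balanced (high C); E diagnoses which
subsystem lags.

Each subsystem's weighted score sum is divided by its weight sum so f and
g live on the same [0, 1] scale as the indicator scores; the subsystem
weights then re-enter through T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional

from .entropy import WeightVector

__all__ = [
    "SubsystemScores",
    "CoordinationResult",
    "subsystem_index",
    "deviation_coefficient",
    "coordination_degree",
    "composite_index",
    "coordinated_development",
    "relative_development",
    "assess_functions",
    "assess_unit",
]

_WEIGHT_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SubsystemScores:
    """Natural and social function indices of one evaluation unit."""

    f_natural: float
    g_social: float
    unit: str = ""

    def __post_init__(self) -> None:
        for name, v in (("f_natural", self.f_natural), ("g_social", self.g_social)):
            if not math.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class CoordinationResult:
    """Full output of the CDD model for one evaluation unit."""

    f_natural: float
    g_social: float
    deviation: float  # C_fg
    coordination: float  # C
    composite: float  # T
    development: float  # D
    relative: float  # E
    unit: str = ""

    def with_unit(self, unit: str) -> "CoordinationResult":
        return replace(self, unit=unit)


def subsystem_index(
    scores: Mapping[str, float], weights: WeightVector, subsystem: str
) -> float:
    """Weighted mean score of one subsystem's indicators.

    ``scores`` maps indicator ids to [0, 1] scores and must cover every
    indicator the weight vector assigns to the subsystem.  The weighted sum
    is normalized by the subsystem weight sum, so constant scores s give
    index s and the result is bounded by the score extremes.
    """
    ids = weights.subsystem_ids(subsystem)
    missing = [i for i in ids if i not in scores]
    if missing:
        raise KeyError(f"scores missing {subsystem} indicator(s): {missing}")
    w_sum = 0.0
    acc = 0.0
    for i in ids:
        w = float(weights.weights[i])
        s = float(scores[i])
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"score for {i} outside [0, 1]: {s}")
        acc += w * s
        w_sum += w
    if w_sum <= 0.0:
        raise ValueError(f"{subsystem} subsystem has zero total weight")
    return acc / w_sum


def _check_fg(f: float, g: float) -> None:
    if not (math.isfinite(f) and math.isfinite(g)):
        raise ValueError("f and g must be finite")
    if f < 0.0 or g < 0.0:
        raise ValueError(f"f and g must be non-negative, got f={f}, g={g}")
    if f + g <= 0.0:
        raise ValueError("deviation undefined for f + g = 0")


def deviation_coefficient(f: float, g: float) -> float:
    """Deviation coefficient C_fg = sqrt(1 - f·g / ((f+g)/2)²).

    Zero when the subsystems are equal; grows toward 1 as one subsystem
    dominates the other.
    """
    _check_fg(f, g)
    mean = 0.5 * (f + g)
    inner = 1.0 - (f * g) / (mean * mean)
    return math.sqrt(max(0.0, inner))


def coordination_degree(f: float, g: float) -> float:
    """Coordination degree C = 1 - C_fg², in [0, 1]; 1 exactly when f = g."""
    c_fg = deviation_coefficient(f, g)
    return min(1.0, max(0.0, 1.0 - c_fg * c_fg))


def composite_index(f: float, g: float, w_natural: float, w_social: float) -> float:
    """Composite evaluation index T = W_natural·f + W_social·g.

    The subsystem weights must partition 1, so T is a convex combination
    lying between f and g.
    """
    if abs(w_natural + w_social - 1.0) > _WEIGHT_SUM_TOL:
        raise ValueError(
            f"subsystem weights must sum to 1, got {w_natural} + {w_social}"
        )
    if w_natural < 0.0 or w_social < 0.0:
        raise ValueError("subsystem weights must be non-negative")
    return w_natural * f + w_social * g


def coordinated_development(coordination: float, composite: float) -> float:
    """Coordinated development degree D = sqrt(C·T)."""
    for name, v in (("coordination", coordination), ("composite", composite)):
        if not math.isfinite(v) or not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return math.sqrt(coordination * composite)


def relative_development(f: float, g: float) -> float:
    """Relative development degree E = f / g (natural over social)."""
    _check_fg(f, g)
    if g <= 0.0:
        raise ValueError("relative development undefined for g = 0")
    return f / g


def assess_functions(
    f: float,
    g: float,
    w_natural: float,
    w_social: float,
    unit: str = "",
) -> CoordinationResult:
    """Run the full CDD chain from subsystem indices f and g."""
    c_fg = deviation_coefficient(f, g)
    c = coordination_degree(f, g)
    t = composite_index(f, g, w_natural, w_social)
    d = coordinated_development(c, t)
    e = relative_development(f, g)
    return CoordinationResult(
        f_natural=f,
        g_social=g,
        deviation=c_fg,
        coordination=c,
        composite=t,
        development=d,
        relative=e,
        unit=unit,
    )


def assess_unit(
    scores: Mapping[str, float],
    weights: WeightVector,
    unit: str = "",
) -> CoordinationResult:
    """Assess one evaluation unit from its indicator scores.

    Computes f and g as the subsystem-weighted means, then the coordination
    C, composite index T, coordinated development degree D and relative
    development degree E.
    """
    f = subsystem_index(scores, weights, "natural")
    g = subsystem_index(scores, weights, "social")
    return assess_functions(f, g, weights.w_natural, weights.w_social, unit=unit)
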