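"""Length-weighted aggregation of station results to whole-river values.

Each monitoring station represents a river segment of length L_i; the
whole-river natural and social function indices are the length-weighted
means

    F = Σ f_i · L_i / L,    G = Σ g_j · L_j / L,

and the overall coordination statistics (C_s, T_s, D_s, E_s) follow by
applying the CDD model to (F, G).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Tuple

from .cdd import CoordinationResult, SubsystemScores, assess_functions

__all__ = ["ReachLayout", "overall_functions", "overall_assessment"]


@dataclass(frozen=True)
class ReachLayout:
    """Partition of a river main stem among its monitoring stations."""

    segment_lengths: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.segment_lengths:
            raise ValueError("layout needs at least one station")
        for station, length in self.segment_lengths.items():
            v = float(length)
            if not math.isfinite(v) or v <= 0.0:
                raise ValueError(
                    f"segment length for {station!r} must be positive, got {length}"
                )

    @property
    def stations(self) -> Tuple[str, ...]:
        return tuple(self.segment_lengths)

    @property
    def total_length(self) -> float:
        return float(sum(self.segment_lengths.values()))

    @classmethod
    def equal_segments(
        cls, stations: Sequence[str], total_length: float
    ) -> "ReachLayout":
        """Split a total length evenly among stations (documented default
        when the true segment partition is unknown)."""
        n = len(stations)
        if n == 0:
            raise ValueError("layout needs at least one station")
        return cls({s: total_length / n for s in stations})


def _as_mapping(
    per_station: Iterable[SubsystemScores] | Mapping[str, SubsystemScores],
) -> Dict[str, SubsystemScores]:
    if isinstance(per_station, Mapping):
        return dict(per_station)
    out: Dict[str, SubsystemScores] = {}
    for entry in per_station:
        if not entry.unit:
            raise ValueError("SubsystemScores entries must carry a station label")
        if entry.unit in out:
            raise ValueError(f"duplicate station {entry.unit!r}")
        out[entry.unit] = entry
    return out


def overall_functions(
    per_station: Iterable[SubsystemScores] | Mapping[str, SubsystemScores],
    layout: ReachLayout,
) -> Tuple[float, float]:
    """Length-weighted whole-river natural and social indices (F, G).

    Every station in the layout must have a subsystem-score entry (keyed by
    station label).  With equal segment lengths this reduces to the
    arithmetic mean; in general F and G are bounded by the per-station
    extremes.
    """
    scores = _as_mapping(per_station)
    missing = [s for s in layout.stations if s not in scores]
    if missing:
        raise KeyError(f"no subsystem scores for station(s): {missing}")
    total = layout.total_length
    f = sum(
        scores[s].f_natural * layout.segment_lengths[s] for s in layout.stations
    ) / total
    g = sum(
        scores[s].g_social * layout.segment_lengths[s] for s in layout.stations
    ) / total
    return f, g


def overall_assessment(
    per_station: Iterable[SubsystemScores] | Mapping[str, SubsystemScores],
    layout: ReachLayout,
    w_natural: float,
    w_social: float,
    unit: str = "overall",
) -> CoordinationResult:
    """Whole-river coordination statistics (C_s, T_s, D_s, E_s).

    Aggregates per-station (f, g) by segment length, then runs the CDD
    chain on the whole-river (F, G).
    """
    f, g = overall_functions(per_station, layout)
    return assess_functions(f, g, w_natural, w_social, unit=unit)
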