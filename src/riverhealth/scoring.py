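"""Indicator registry and conversion of raw observations to score matrices.

The assessment works on 16 indicators (C1–C16) split over a natural
subsystem (hydrology, physical form, water quality, aquatic life; C1–C10)
and a social subsystem (flood control, pollutant loading, water supply,
landscape; C11–C16).  Each indicator declares a scoring rule:

``ladder``
    a single raw value scored on one threshold ladder;
``parabolic``
    the water-resource utilization parabola;
``composite_min`` / ``composite_mean``
    several components (named concentrations, flow periods, or sampling
    points) scored individually and combined by the minimum or the mean;
``passthrough``
    the value is already a [0, 1] score computed upstream (riparian-status
    composites, questionnaire means) and is only range-validated.

Scores form an (evaluation unit × indicator) matrix, one row per
station-year, which feeds entropy weighting and the coordination model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .ladders import (
    LadderError,
    ParabolicRule,
    ThresholdLadder,
    score_composite_mean,
    score_composite_min,
)

__all__ = [
    "RawObservation",
    "IndicatorDefinition",
    "IndicatorRegistry",
    "build_score_matrix",
    "validate_score_matrix",
]

Rule = Literal["ladder", "parabolic", "composite_min", "composite_mean", "passthrough"]
Subsystem = Literal["natural", "social"]

#: Component name used by single-value indicators.
DEFAULT_COMPONENT = "value"


@dataclass(frozen=True)
class RawObservation:
    """One indicator observation at one station in one year.

    ``components`` maps component names to raw values: single-component
    indicators use one ``"value"`` entry, composite indicators carry one
    entry per concentration / flow period / sampling point.
    """

    station: str
    year: int
    indicator_id: str
    components: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError(
                f"{self.indicator_id}@{self.station}/{self.year}: "
                "observation has no components"
            )
        for name, value in self.components.items():
            v = float(value)
            if not math.isfinite(v):
                raise ValueError(
                    f"{self.indicator_id}@{self.station}/{self.year}: "
                    f"component {name!r} is not finite"
                )
            if v < 0.0:
                raise ValueError(
                    f"{self.indicator_id}@{self.station}/{self.year}: "
                    f"component {name!r} is negative ({v})"
                )


@dataclass(frozen=True)
class IndicatorDefinition:
    """Scoring recipe for one indicator."""

    indicator_id: str
    name: str
    criterion: str
    subsystem: Subsystem
    rule: Rule
    ladders: Mapping[str, ThresholdLadder] = field(default_factory=dict)
    shared_ladder: Optional[ThresholdLadder] = None
    parabola: Optional[ParabolicRule] = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.rule == "ladder" and DEFAULT_COMPONENT not in self.ladders:
            raise LadderError(
                f"{self.indicator_id}: rule 'ladder' needs a '{DEFAULT_COMPONENT}' ladder"
            )
        if self.rule == "parabolic" and self.parabola is None:
            raise LadderError(f"{self.indicator_id}: rule 'parabolic' needs a parabola")
        if self.rule in ("composite_min", "composite_mean"):
            if not self.ladders and self.shared_ladder is None:
                raise LadderError(
                    f"{self.indicator_id}: composite rule needs component "
                    "ladders or a shared ladder"
                )

    @property
    def components(self) -> Tuple[str, ...]:
        """Declared component names (empty for free-form shared-ladder rules)."""
        if self.ladders:
            return tuple(self.ladders)
        return (DEFAULT_COMPONENT,) if self.shared_ladder is None else ()

    def component_ladder(self, component: str) -> ThresholdLadder:
        if component in self.ladders:
            return self.ladders[component]
        if self.shared_ladder is not None:
            return self.shared_ladder
        raise KeyError(f"{self.indicator_id}: unknown component {component!r}")

    def score(self, observation: RawObservation) -> float:
        """Apply this indicator's rule to one observation."""
        if observation.indicator_id != self.indicator_id:
            raise ValueError(
                f"observation is for {observation.indicator_id}, "
                f"not {self.indicator_id}"
            )
        comps = dict(observation.components)
        if self.rule in ("ladder", "parabolic", "passthrough"):
            if set(comps) != {DEFAULT_COMPONENT}:
                raise ValueError(
                    f"{self.indicator_id}: expected a single "
                    f"'{DEFAULT_COMPONENT}' component, got {sorted(comps)}"
                )
            value = comps[DEFAULT_COMPONENT]
            if self.rule == "ladder":
                return self.ladders[DEFAULT_COMPONENT].score(value)
            if self.rule == "parabolic":
                assert self.parabola is not None
                return self.parabola.score(value)
            score = float(value)
            if not 0.0 <= score <= 1.0:
                raise ValueError(
                    f"{self.indicator_id}: pre-computed score {score} "
                    "outside [0, 1]"
                )
            return score
        # composite rules
        if self.ladders and set(comps) != set(self.ladders):
            raise ValueError(
                f"{self.indicator_id}: component set {sorted(comps)} does not "
                f"match declared components {sorted(self.ladders)}"
            )
        scores = [
            self.component_ladder(name).score(value) for name, value in comps.items()
        ]
        if self.rule == "composite_min":
            return score_composite_min(scores)
        return score_composite_mean(scores)


class IndicatorRegistry:
    """Ordered collection of indicator definitions for one assessment."""

    def __init__(self, definitions: Iterable[IndicatorDefinition]):
        self._defs: Dict[str, IndicatorDefinition] = {}
        for d in definitions:
            if d.indicator_id in self._defs:
                raise LadderError(f"duplicate indicator {d.indicator_id}")
            self._defs[d.indicator_id] = d
        if not self._defs:
            raise LadderError("registry has no indicators")

    def __iter__(self):
        return iter(self._defs.values())

    def __len__(self) -> int:
        return len(self._defs)

    def __contains__(self, indicator_id: str) -> bool:
        return indicator_id in self._defs

    def __getitem__(self, indicator_id: str) -> IndicatorDefinition:
        try:
            return self._defs[indicator_id]
        except KeyError:
            raise KeyError(f"indicator {indicator_id!r} not in registry") from None

    @property
    def indicator_ids(self) -> Tuple[str, ...]:
        return tuple(self._defs)

    def ids(self, subsystem: Subsystem) -> Tuple[str, ...]:
        return tuple(d.indicator_id for d in self if d.subsystem == subsystem)

    @property
    def natural_ids(self) -> Tuple[str, ...]:
        return self.ids("natural")

    @property
    def social_ids(self) -> Tuple[str, ...]:
        return self.ids("social")

    def require(self, expected_ids: Sequence[str]) -> "IndicatorRegistry":
        """Check that every expected indicator is present (by id)."""
        missing = [i for i in expected_ids if i not in self._defs]
        if missing:
            raise LadderError(
                "registry is missing indicator(s): " + ", ".join(missing)
            )
        return self


def build_score_matrix(
    observations: Iterable[RawObservation],
    registry: IndicatorRegistry,
    missing_policy: Literal["error", "carry-forward"] = "error",
) -> pd.DataFrame:
    """Score raw observations into an (evaluation unit × indicator) matrix.

    Rows are indexed by ``(station, year)``; columns follow the registry's
    indicator order.  Every unit must have an observation for every
    indicator unless ``missing_policy="carry-forward"``, in which case the
    most recent earlier year of the same station fills the gap (biological
    surveys are commonly reused across years).
    """
    scored: Dict[Tuple[str, int], Dict[str, float]] = {}
    for obs in observations:
        if obs.indicator_id not in registry:
            raise KeyError(f"observation for unknown indicator {obs.indicator_id!r}")
        unit = (str(obs.station), int(obs.year))
        row = scored.setdefault(unit, {})
        if obs.indicator_id in row:
            raise ValueError(
                f"duplicate observation for {obs.indicator_id} at "
                f"{unit[0]}/{unit[1]}"
            )
        row[obs.indicator_id] = registry[obs.indicator_id].score(obs)
    if not scored:
        raise ValueError("no observations given")

    units = sorted(scored, key=lambda u: (u[1], u[0]))  # year-major, station
    columns = list(registry.indicator_ids)
    for station, year in units:
        row = scored[(station, year)]
        for ind in columns:
            if ind in row:
                continue
            if missing_policy == "carry-forward":
                earlier = sorted(
                    y for s, y in units if s == station and y < year
                    and ind in scored[(s, y)]
                )
                if earlier:
                    row[ind] = scored[(station, earlier[-1])][ind]
                    continue
            raise ValueError(
                f"missing indicator {ind} for unit {station}/{year} "
                f"(missing_policy={missing_policy!r})"
            )
    index = pd.MultiIndex.from_tuples(units, names=["station", "year"])
    frame = pd.DataFrame(
        [[scored[u][ind] for ind in columns] for u in units],
        index=index,
        columns=columns,
    )
    return frame


def validate_score_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Reject score matrices with entries outside [0, 1] or non-finite."""
    values = matrix.to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError("score matrix is empty")
    if not ((values >= 0.0) & (values <= 1.0)).all():
        raise ValueError("score matrix has entries outside [0, 1]")
    return matrix
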