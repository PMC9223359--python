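"""Structured-text configuration: indicator thresholds and grade schemes.

The threshold config is a YAML document with one block per indicator
(id, subsystem, criterion, rule, orientation, anchors / components /
parabola).  Ladders declared in percent units are converted to fractions
on load; all raw observations are fractions internally.  Loading is
order-insensitive: anchors are canonically re-sorted by score.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, List, Literal, Optional, Sequence, Tuple, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .grades import GradeScheme
from .ladders import LadderError, ParabolicRule, ThresholdLadder
from .scoring import DEFAULT_COMPONENT, IndicatorDefinition, IndicatorRegistry

__all__ = [
    "DEFAULT_INDICATOR_IDS",
    "load_threshold_config",
    "default_registry",
    "load_grade_scheme",
]

#: The canonical 16-indicator system: 10 natural (C1-C10), 6 social (C11-C16).
DEFAULT_INDICATOR_IDS: Tuple[str, ...] = tuple(f"C{i}" for i in range(1, 17))

AnchorMap = Dict[float, float]


class ParabolaModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    coef_a: float
    coef_b: float
    scale: float = 100.0
    cutoff: float = 0.6


class IndicatorModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    name: str = ""
    criterion: str = ""
    subsystem: Literal["natural", "social"]
    rule: Literal["ladder", "parabolic", "composite_min", "composite_mean", "passthrough"]
    orientation: Optional[Literal["benefit", "cost"]] = None
    units: Literal["raw", "percent"] = "raw"
    anchors: Optional[AnchorMap] = None
    components: Optional[Dict[str, AnchorMap]] = None
    shared_ladder: Optional[AnchorMap] = None
    parabola: Optional[ParabolaModel] = None
    notes: str = ""

    @model_validator(mode="after")
    def _rule_fields(self) -> "IndicatorModel":
        if self.rule == "ladder" and self.anchors is None:
            raise ValueError(f"{self.id}: rule 'ladder' requires anchors")
        if self.rule == "parabolic" and self.parabola is None:
            raise ValueError(f"{self.id}: rule 'parabolic' requires a parabola block")
        if self.rule in ("composite_min", "composite_mean"):
            if self.components is None and self.shared_ladder is None:
                raise ValueError(
                    f"{self.id}: composite rules require components or a shared_ladder"
                )
        if self.rule in ("ladder", "composite_min", "composite_mean") and (
            self.orientation is None
        ):
            raise ValueError(f"{self.id}: rule {self.rule!r} requires an orientation")
        return self


class ThresholdConfigModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    indicators: List[IndicatorModel]


def _scale_anchors(anchors: AnchorMap, units: str) -> AnchorMap:
    if units == "percent":
        return {float(s): float(t) / 100.0 for s, t in anchors.items()}
    return {float(s): float(t) for s, t in anchors.items()}


def _build_definition(model: IndicatorModel) -> IndicatorDefinition:
    ladders: Dict[str, ThresholdLadder] = {}
    shared: Optional[ThresholdLadder] = None
    parabola: Optional[ParabolicRule] = None
    try:
        if model.rule == "ladder":
            assert model.anchors is not None
            ladders[DEFAULT_COMPONENT] = ThresholdLadder(
                model.id, model.orientation, _scale_anchors(model.anchors, model.units)
            )
        elif model.rule in ("composite_min", "composite_mean"):
            for comp, anchors in (model.components or {}).items():
                ladders[comp] = ThresholdLadder(
                    f"{model.id}.{comp}",
                    model.orientation,
                    _scale_anchors(anchors, model.units),
                )
            if model.shared_ladder is not None:
                shared = ThresholdLadder(
                    model.id,
                    model.orientation,
                    _scale_anchors(model.shared_ladder, model.units),
                )
        elif model.rule == "parabolic":
            assert model.parabola is not None
            parabola = ParabolicRule(
                coef_a=model.parabola.coef_a,
                coef_b=model.parabola.coef_b,
                scale=model.parabola.scale,
                cutoff=model.parabola.cutoff,
            )
    except LadderError as exc:
        raise LadderError(f"indicator {model.id}: {exc}") from exc
    return IndicatorDefinition(
        indicator_id=model.id,
        name=model.name,
        criterion=model.criterion,
        subsystem=model.subsystem,
        rule=model.rule,
        ladders=ladders,
        shared_ladder=shared,
        parabola=parabola,
        notes=model.notes,
    )


def _default_config_text() -> str:
    return (
        resources.files("riverhealth.data")
        .joinpath("default_thresholds.yaml")
        .read_text(encoding="utf-8")
    )


def load_threshold_config(
    path: Union[str, Path, None] = None,
    expected_ids: Optional[Sequence[str]] = DEFAULT_INDICATOR_IDS,
) -> IndicatorRegistry:
    """Load and validate an indicator threshold configuration.

    Parameters
    ----------
    path:
        YAML file to load; ``None`` loads the packaged default criteria.
    expected_ids:
        Indicator ids that must all be present (default: C1-C16).  Pass
        ``None`` to accept any indicator set, e.g. for reduced systems.

    Raises
    ------
    LadderError
        On non-monotone ladders (with the indicator named), unknown rule
        kinds, or missing expected indicators.
    """
    if path is None:
        text = _default_config_text()
        source = "<packaged default>"
    else:
        source = str(path)
        text = Path(path).read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text)
        model = ThresholdConfigModel.model_validate(raw)
    except Exception as exc:
        raise LadderError(f"cannot parse threshold config {source}: {exc}") from exc
    registry = IndicatorRegistry(_build_definition(m) for m in model.indicators)
    if expected_ids is not None:
        registry.require(expected_ids)
    return registry


def default_registry() -> IndicatorRegistry:
    """The packaged default 16-indicator registry."""
    return load_threshold_config(None)


class GradeSchemeModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    state_bins: Optional[List[Tuple[float, float, str]]] = None
    coordination_bins: Optional[List[Tuple[float, float, str]]] = None
    relative_thresholds: Optional[Tuple[float, float]] = None
    relative_labels: Optional[Tuple[str, str, str]] = None


def load_grade_scheme(path: Union[str, Path, None] = None) -> GradeScheme:
    """Load a grade scheme from YAML, or the default five/three-grade one.

    Any omitted section falls back to the default scheme, so a config may
    override just the bins it needs to change.
    """
    if path is None:
        return GradeScheme()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    model = GradeSchemeModel.model_validate(raw)
    base = GradeScheme()
    return GradeScheme(
        state_bins=tuple(model.state_bins) if model.state_bins else base.state_bins,
        coordination_bins=(
            tuple(model.coordination_bins)
            if model.coordination_bins
            else base.coordination_bins
        ),
        relative_thresholds=model.relative_thresholds or base.relative_thresholds,
        relative_labels=model.relative_labels or base.relative_labels,
    )
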