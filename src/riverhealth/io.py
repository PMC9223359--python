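"""CSV I/O and the end-to-end assessment pipeline.

All tables are comma-separated UTF-8 with a mandatory header row and "."
as the decimal separator.  Observations use the long format
``station,year,indicator,component,value`` (one row per component);
layouts use ``station,segment_length_km``.  Report files are written with
a configurable fixed decimal precision (default 3).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Literal, Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict

from .aggregate import ReachLayout, overall_assessment
from .cdd import CoordinationResult, SubsystemScores, assess_unit
from .config import load_grade_scheme, load_threshold_config
from .entropy import WeightVector, entropy_weights
from .fixtures import LhasaFixture, lhasa_fixture
from .grades import GradeScheme, grade_coordination, grade_relative, grade_state
from .scoring import IndicatorRegistry, RawObservation, build_score_matrix
from . import cdd

__all__ = [
    "read_observations",
    "write_observations",
    "read_layout",
    "weights_frame",
    "assessment_frame",
    "reference_assessment",
    "RunConfig",
    "run_assessment",
]

logger = logging.getLogger("riverhealth")

OBSERVATION_COLUMNS = ["station", "year", "indicator", "component", "value"]


def read_observations(path: Union[str, Path]) -> List[RawObservation]:
    """Read a long-format observations CSV into raw observations."""
    frame = pd.read_csv(path)
    missing = [c for c in OBSERVATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"observations CSV {path} lacks column(s): {missing}")
    observations: List[RawObservation] = []
    grouped = frame.groupby(["station", "year", "indicator"], sort=False)
    for (station, year, indicator), block in grouped:
        components = {}
        for _, row in block.iterrows():
            name = str(row["component"])
            if name in components:
                raise ValueError(
                    f"duplicate component {name!r} for {indicator} at "
                    f"{station}/{year}"
                )
            components[name] = float(row["value"])
        observations.append(
            RawObservation(
                station=str(station),
                year=int(year),
                indicator_id=str(indicator),
                components=components,
            )
        )
    return observations


def write_observations(
    observations: Iterable[RawObservation], path: Union[str, Path]
) -> Path:
    """Write observations in the long CSV dialect the reader accepts."""
    rows = [
        {
            "station": o.station,
            "year": o.year,
            "indicator": o.indicator_id,
            "component": name,
            "value": value,
        }
        for o in observations
        for name, value in o.components.items()
    ]
    frame = pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.12g")
    return path


def read_layout(path: Union[str, Path]) -> ReachLayout:
    """Read a reach layout CSV (``station,segment_length_km``)."""
    frame = pd.read_csv(path)
    for col in ("station", "segment_length_km"):
        if col not in frame.columns:
            raise ValueError(f"layout CSV {path} lacks column {col!r}")
    return ReachLayout(
        {str(r["station"]): float(r["segment_length_km"]) for _, r in frame.iterrows()}
    )


def weights_frame(weights: WeightVector, registry: IndicatorRegistry) -> pd.DataFrame:
    """Tabulate entropy weights: indicator, criterion, subsystem, entropy, weight."""
    rows = []
    for ind in weights.weights.index:
        d = registry[ind]
        rows.append(
            {
                "indicator": ind,
                "name": d.name,
                "criterion": d.criterion,
                "subsystem": d.subsystem,
                "entropy": float(weights.entropies[ind]),
                "weight": float(weights.weights[ind]),
            }
        )
    return pd.DataFrame(rows)


def _result_row(result: CoordinationResult, scheme: GradeScheme) -> Dict[str, object]:
    return {
        "f_natural": result.f_natural,
        "g_social": result.g_social,
        "deviation_Cfg": result.deviation,
        "coordination_C": result.coordination,
        "composite_T": result.composite,
        "development_D": result.development,
        "relative_E": result.relative,
        "state_grade": grade_state(result.composite, scheme),
        "coordination_grade": grade_coordination(result.development, scheme),
        "relative_grade": grade_relative(result.relative, scheme),
    }


def assessment_frame(
    results: Sequence[CoordinationResult], scheme: Optional[GradeScheme] = None
) -> pd.DataFrame:
    """Tabulate coordination results with their grade labels."""
    scheme = scheme or GradeScheme()
    rows = []
    for r in results:
        row: Dict[str, object] = {"unit": r.unit}
        row.update(_result_row(r, scheme))
        rows.append(row)
    return pd.DataFrame(rows)


def reference_assessment(
    fixture: Optional[LhasaFixture] = None, scheme: Optional[GradeScheme] = None
) -> pd.DataFrame:
    """Re-derive the published whole-river statistics from printed inputs.

    Temporal rows start from the printed per-year social function g and
    relative development E (f = g·E); spatial rows start from the printed
    per-station natural function f and E (g = f/E).  Everything else runs
    through the package's coordination chain with the printed 0.67/0.33
    subsystem weights, ready for side-by-side comparison with the printed
    T and D columns.
    """
    fixture = fixture or lhasa_fixture()
    scheme = scheme or GradeScheme()
    w_nat, w_soc = fixture.weights
    results: List[CoordinationResult] = []
    for year in fixture.years:
        g = fixture.g_by_year[year]
        f = fixture.f_by_year(year)
        results.append(cdd.assess_functions(f, g, w_nat, w_soc, unit=str(year)))
    for pos in fixture.positions:
        f = fixture.f_spatial[pos]
        g = fixture.g_spatial_implied(pos)
        results.append(cdd.assess_functions(f, g, w_nat, w_soc, unit=pos))
    frame = assessment_frame(results, scheme)
    printed_T = [fixture.T_by_year[y] for y in fixture.years] + [
        fixture.T_spatial[p] for p in fixture.positions
    ]
    printed_D = [fixture.D_by_year[y] for y in fixture.years] + [
        fixture.D_spatial[p] for p in fixture.positions
    ]
    frame["printed_T"] = printed_T
    frame["printed_D"] = printed_D
    return frame


class RunConfig(BaseModel):
    """Inputs and options for one end-to-end assessment run."""

    model_config = ConfigDict(extra="forbid")

    observations: Path
    thresholds: Optional[Path] = None
    layout: Optional[Path] = None
    grades: Optional[Path] = None
    out_dir: Path = Path("riverhealth_out")
    missing_policy: Literal["error", "carry-forward"] = "error"
    precision: int = 3


def run_assessment(config: RunConfig) -> Dict[str, Path]:
    """Run the full pipeline and write the report files.

    Stages: load config → read observations → score matrix → entropy
    weights → per-unit coordination results → length-weighted whole-river
    results per year.  Returns the paths of the four CSV reports
    (``scores``, ``weights``, ``units``, ``overall``).
    """
    if not Path(config.observations).exists():
        raise FileNotFoundError(f"observations file {config.observations} not found")
    registry = load_threshold_config(config.thresholds)
    scheme = load_grade_scheme(config.grades)
    logger.info("loaded registry with %d indicators", len(registry))

    observations = read_observations(config.observations)
    logger.info("read %d observations", len(observations))

    matrix = build_score_matrix(observations, registry, config.missing_policy)
    logger.info("scored %d evaluation units", matrix.shape[0])

    weights = entropy_weights(matrix, registry)
    logger.info(
        "entropy weights: W_natural=%.3f W_social=%.3f",
        weights.w_natural,
        weights.w_social,
    )

    results = [
        assess_unit(matrix.loc[unit].to_dict(), weights, unit=f"{unit[0]}/{unit[1]}")
        for unit in matrix.index
    ]

    stations = sorted({s for s, _ in matrix.index})
    if config.layout is not None:
        layout = read_layout(config.layout)
    else:
        layout = ReachLayout.equal_segments(stations, float(len(stations)))
        logger.info("no layout given: assuming equal segment lengths")
    years = sorted({y for _, y in matrix.index})
    overall_results = []
    for year in years:
        per_station = {}
        for (station, y), result in zip(matrix.index, results):
            if y == year:
                per_station[station] = SubsystemScores(
                    f_natural=result.f_natural,
                    g_social=result.g_social,
                    unit=station,
                )
        overall_results.append(
            overall_assessment(
                per_station,
                layout,
                weights.w_natural,
                weights.w_social,
                unit=str(year),
            )
        )
    logger.info("aggregated %d whole-river results", len(overall_results))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = f"%.{config.precision}f"
    paths = {
        "scores": out / "scores.csv",
        "weights": out / "weights.csv",
        "units": out / "assessment_units.csv",
        "overall": out / "assessment_overall.csv",
    }
    matrix.reset_index().to_csv(paths["scores"], index=False, float_format=fmt)
    weights_frame(weights, registry).to_csv(
        paths["weights"], index=False, float_format=fmt
    )
    assessment_frame(results, scheme).to_csv(
        paths["units"], index=False, float_format=fmt
    )
    assessment_frame(overall_results, scheme).to_csv(
        paths["overall"], index=False, float_format=fmt
    )
    logger.info("reports written to %s", out)
    return paths
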