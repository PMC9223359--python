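"""Published Lhasa River assessment values, packaged for regression tests.

The bundle transcribes the whole-river statistics reported for the Lhasa
River (2011–2014, three main-stem stations): per-year overall social
function g and relative development E (from which f, T and D re-derive),
the per-station natural function f, relative development E and state index
T, the printed T/D values themselves, and the 0.67/0.33 natural/social
subsystem weight split.  Values are verbatim transcriptions and are never
recomputed in place.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Tuple

import yaml

__all__ = ["LhasaFixture", "lhasa_fixture"]


@dataclass(frozen=True)
class LhasaFixture:
    """Printed reference values for the Lhasa River assessment."""

    #: (natural, social) subsystem weight sums.
    weights: Tuple[float, float]
    years: Tuple[int, ...]
    #: Whole-river social function per year.
    g_by_year: Dict[int, float]
    #: Whole-river relative development degree per year.
    E_by_year: Dict[int, float]
    #: Whole-river state index (composite T) per year.
    T_by_year: Dict[int, float]
    #: Whole-river coordinated development degree per year.
    D_by_year: Dict[int, float]
    positions: Tuple[str, ...]
    #: Per-station natural function (upstream/midstream/downstream).
    f_spatial: Dict[str, float]
    E_spatial: Dict[str, float]
    T_spatial: Dict[str, float]
    D_spatial: Dict[str, float]
    stations: Tuple[str, ...]
    main_stem_km: float

    def f_by_year(self, year: int) -> float:
        """Whole-river natural function implied by printed g and E (f = g·E)."""
        return self.g_by_year[year] * self.E_by_year[year]

    def g_spatial_implied(self, position: str) -> float:
        """Per-station social function implied by printed f and E (g = f/E)."""
        return self.f_spatial[position] / self.E_spatial[position]


def lhasa_fixture() -> LhasaFixture:
    """Load the packaged Lhasa River reference-value bundle."""
    text = (
        resources.files("riverhealth.data")
        .joinpath("lhasa_fixture.yaml")
        .read_text(encoding="utf-8")
    )
    raw = yaml.safe_load(text)
    temporal = raw["temporal"]
    spatial = raw["spatial"]
    return LhasaFixture(
        weights=(
            float(raw["subsystem_weights"]["natural"]),
            float(raw["subsystem_weights"]["social"]),
        ),
        years=tuple(int(y) for y in temporal["years"]),
        g_by_year={int(k): float(v) for k, v in temporal["g_social"].items()},
        E_by_year={int(k): float(v) for k, v in temporal["relative"].items()},
        T_by_year={int(k): float(v) for k, v in temporal["composite"].items()},
        D_by_year={int(k): float(v) for k, v in temporal["development"].items()},
        positions=tuple(spatial["positions"]),
        f_spatial={str(k): float(v) for k, v in spatial["f_natural"].items()},
        E_spatial={str(k): float(v) for k, v in spatial["relative"].items()},
        T_spatial={str(k): float(v) for k, v in spatial["composite"].items()},
        D_spatial={str(k): float(v) for k, v in spatial["development"].items()},
        stations=tuple(raw["river"]["stations"]),
        main_stem_km=float(raw["river"]["main_stem_km"]),
    )
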