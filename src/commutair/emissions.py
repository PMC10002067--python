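"""Per-passenger exhaust PM emissions of motorised transport modes.

The emission attributable to one passenger over a two-way trip is

    E = EF × d / p      [g PM per passenger]

with EF the exhaust emission factor (g km^-1, stratified by vehicle, fuel
and Euro standard, from emission-inventory guidebook values), d the two-way
route distance (km) and p the vehicle occupancy (1 for cars and motorcycles,
50 for buses by default).  Electric vehicles have EF = 0.  The engine keeps
full precision; rounding happens only when a table is rendered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, ParameterError
from .sensor_io import EmissionFactor

#: the default (vehicle, fuel) columns of the rendered emission table
DEFAULT_COLUMNS: tuple[tuple[str, str, str], ...] = (
    ("car", "petrol", "Euro 5"),
    ("car", "diesel", "Euro 5"),
    ("bus", "biodiesel", "Euro 5"),
    ("bus", "diesel", "Euro 5"),
    ("bus", "CNG", "Euro 5"),
    ("motorcycle", "petrol", "Euro 5"),
)


class EmissionFactorSet:
    """Lookup of emission factors keyed by (vehicle, fuel, euro standard)."""

    def __init__(self, factors: Iterable[EmissionFactor]):
        self._factors: dict[tuple[str, str, str], EmissionFactor] = {}
        for factor in factors:
            self._factors[factor.key] = factor

    def __getitem__(self, key: tuple[str, str, str]) -> EmissionFactor:
        try:
            return self._factors[key]
        except KeyError:
            raise ConfigError(
                f"unknown emission-factor key {key!r}; available: {sorted(self._factors)}"
            ) from None

    def __iter__(self):
        return iter(self._factors.values())

    def __len__(self) -> int:
        return len(self._factors)

    @property
    def keys(self) -> tuple[tuple[str, str, str], ...]:
        return tuple(self._factors)


@dataclass(frozen=True)
class EmissionResult:
    """Per-passenger emission of one (route, vehicle/fuel/euro) combination."""

    route_id: str
    vehicle: str
    fuel: str
    euro: str
    distance_km: float
    passengers: int
    emission_g: float


def emission_per_passenger(ef: float, distance_km: float, passengers: int) -> float:
    """E = EF × d / p, in grams of PM per passenger."""
    if ef < 0:
        raise ParameterError(f"emission factor must be >= 0, got {ef}")
    if distance_km < 0:
        raise ParameterError(f"distance must be >= 0, got {distance_km}")
    if passengers < 1:
        raise ParameterError(f"passengers must be >= 1, got {passengers}")
    return ef * distance_km / passengers


def factor_ratio(
    factors: EmissionFactorSet, key_a: tuple[str, str, str], key_b: tuple[str, str, str]
) -> float:
    """How many times more PM per km key_a emits than key_b."""
    ef_a = factors[key_a].ef
    ef_b = factors[key_b].ef
    if ef_b == 0:
        raise ParameterError(f"denominator factor {key_b!r} has zero emission factor")
    return ef_a / ef_b


def route_emission_table(
    routes: Sequence[tuple[str, float]],
    factors: EmissionFactorSet,
    occupancy: Mapping[str, int],
    columns: Sequence[tuple[str, str, str]] = DEFAULT_COLUMNS,
) -> list[EmissionResult]:
    """Full cross of routes × vehicle/fuel/euro combinations.

    ``routes`` are (route_id, two-way distance km) pairs; ``occupancy`` maps
    vehicle type to passenger count.  Unknown factor keys raise
    :class:`ConfigError` listing the available ones.
    """
    results = []
    for route_id, distance_km in routes:
        for key in columns:
            factor = factors[key]
            passengers = int(occupancy.get(factor.vehicle, 1))
            results.append(
                EmissionResult(
                    route_id=route_id,
                    vehicle=factor.vehicle,
                    fuel=factor.fuel,
                    euro=factor.euro,
                    distance_km=distance_km,
                    passengers=passengers,
                    emission_g=emission_per_passenger(factor.ef, distance_km, passengers),
                )
            )
    return results


def emission_table_frame(results: Sequence[EmissionResult]) -> pd.DataFrame:
    """Wide table: one row per route, one column per (vehicle, fuel)."""
    frame = pd.DataFrame(
        {
            "route_id": [r.route_id for r in results],
            "distance_km": [r.distance_km for r in results],
            "column": [f"{r.vehicle}/{r.fuel}" for r in results],
            "emission_g": [r.emission_g for r in results],
        }
    )
    wide = frame.pivot_table(
        index=["route_id", "distance_km"], columns="column", values="emission_g", sort=False
    ).reset_index()
    wide.columns.name = None
    return wide
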