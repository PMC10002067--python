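"""Commuter inhaled-dose modelling and cabin indoor/outdoor ratios.

The inhaled dose over a trip is the product

    D_PM = PM_out × I/O × t × IR        [µg]

with PM_out the mean outdoor concentration (µg m^-3), I/O the cabin
indoor/outdoor ratio of the transport mode, t the travel time (h) and IR the
mode-specific inhalation rate (m^3 h^-1).  When the cabin concentration was
measured directly, the caller passes it as PM_out with I/O = 1 ("measured
indoor" mode) — the configuration used to summarise instrumented bus
campaigns; deriving the cabin level from outdoor sensors through configured
I/O ratios is the deployment mode.

Doses are exactly multilinear: doubling any factor doubles the dose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .sensor_io import FLAG_OK, InhalationTable, IORatioTable, SensorRecord

logger = logging.getLogger(__name__)

SIZE_FRACTIONS = ("pm25", "pm10")


@dataclass(frozen=True)
class TripSummary:
    """Per-route, per-period concentration summary of one instrumented trip.

    Travel time (minutes) and distance (km) are two-way totals.  Means and
    SDs are per size fraction (µg m^-3); missing values (excluded periods)
    are None.
    """

    route_id: str
    start_label: str
    travel_time_min: float | None
    distance_km: float | None = None
    mode: str = "bus"
    indoor_mean: Mapping[str, float] | None = None
    indoor_sd: Mapping[str, float] | None = None
    outdoor_mean: Mapping[str, float] | None = None
    outdoor_sd: Mapping[str, float] | None = None
    t_range: tuple[float, float] | None = None
    rh_range: tuple[float, float] | None = None
    excluded: bool = False

    @property
    def io(self) -> dict[str, float] | None:
        """Derived indoor/outdoor ratio per size fraction, where defined."""
        if self.indoor_mean is None or self.outdoor_mean is None:
            return None
        return {
            f: io_ratio(self.indoor_mean[f], self.outdoor_mean[f]) for f in SIZE_FRACTIONS
        }


@dataclass(frozen=True)
class DoseResult:
    """Inhaled dose of one (route, period, mode) two-way trip, µg."""

    route_id: str
    start_label: str
    mode: str
    dose_pm25: float
    dose_pm10: float

    def __post_init__(self) -> None:
        if self.dose_pm25 < 0 or self.dose_pm10 < 0:
            raise ParameterError("doses must be non-negative")


def mean_concentration(records: Sequence[SensorRecord], fraction: str) -> float:
    """Mean of ok-flagged records for one size fraction (µg m^-3)."""
    if fraction not in SIZE_FRACTIONS:
        raise ParameterError(f"fraction must be one of {SIZE_FRACTIONS}")
    values = [getattr(r, fraction) for r in records if r.flag == FLAG_OK]
    if not values:
        raise ParameterError("no ok-flagged records to average")
    return float(np.mean(values))


def io_ratio(indoor, outdoor) -> float:
    """Indoor/outdoor concentration ratio from means or record streams."""
    if isinstance(indoor, (list, tuple)) and indoor and isinstance(indoor[0], SensorRecord):
        raise ParameterError("pass mean_concentration(records, fraction), not raw records")
    indoor_mean = float(np.mean(np.asarray(indoor, dtype=float)))
    outdoor_mean = float(np.mean(np.asarray(outdoor, dtype=float)))
    if outdoor_mean <= 0:
        raise ParameterError("outdoor mean must be positive for an I/O ratio")
    return indoor_mean / outdoor_mean


def inhaled_dose(pm_out: float, io: float, travel_time_h: float, ir: float) -> float:
    """Dose (µg) = outdoor concentration × I/O × time (h) × inhalation rate."""
    for name, value in (("pm_out", pm_out), ("io", io),
                        ("travel_time_h", travel_time_h), ("ir", ir)):
        if value < 0:
            raise ParameterError(f"{name} must be non-negative, got {value}")
    return pm_out * io * travel_time_h * ir


def trips_from_frame(frame: pd.DataFrame) -> list[TripSummary]:
    """Build TripSummary objects from the packaged bus-campaign table schema."""
    trips = []
    for row in frame.itertuples(index=False):
        excluded = bool(row.excluded)
        trips.append(
            TripSummary(
                route_id=row.route_id,
                start_label=row.start_label,
                travel_time_min=None if excluded else float(row.travel_time_min),
                distance_km=float(row.distance_km),
                indoor_mean=None if excluded else {"pm25": float(row.pm25_in), "pm10": float(row.pm10_in)},
                indoor_sd=None if excluded else {"pm25": float(row.pm25_in_sd), "pm10": float(row.pm10_in_sd)},
                outdoor_mean=None if excluded else {"pm25": float(row.pm25_out), "pm10": float(row.pm10_out)},
                outdoor_sd=None if excluded else {"pm25": float(row.pm25_out_sd), "pm10": float(row.pm10_out_sd)},
                t_range=None if excluded else (float(row.t_min), float(row.t_max)),
                rh_range=None if excluded else (float(row.rh_min), float(row.rh_max)),
                excluded=excluded,
            )
        )
    return trips


def trip_dose_table(
    trips: Iterable[TripSummary],
    ir_table: InhalationTable,
    io_table: IORatioTable,
    modes: Sequence[str] = ("bus",),
    mode_travel_times: Mapping[str, Mapping[tuple[str, str], float]] | None = None,
    measured_indoor: bool = True,
) -> list[DoseResult]:
    """Two-way inhaled doses for each (trip, mode) combination.

    For buses with measured cabin concentrations (``measured_indoor=True``)
    the dose uses the indoor mean directly (I/O = 1 on the measured value);
    every other mode — and buses in deployment mode — uses the outdoor mean
    and the configured I/O ratio.  Travel times for non-bus modes are never
    guessed: they must be supplied via ``mode_travel_times`` keyed
    ``mode -> {(route_id, start_label): minutes}``; a missing time skips that
    row with a logged reason while the remaining rows are still produced.
    Excluded trips are omitted with a logged reason.
    """
    results: list[DoseResult] = []
    for trip in trips:
        if trip.excluded:
            logger.info("skipping %s %s: period excluded by quality flag",
                        trip.route_id, trip.start_label)
            continue
        for mode in modes:
            if mode == "bus" and trip.travel_time_min is not None:
                minutes = trip.travel_time_min
            else:
                per_mode = (mode_travel_times or {}).get(mode, {})
                minutes = per_mode.get((trip.route_id, trip.start_label))
            if minutes is None:
                logger.warning("no travel time for mode %r on %s %s; row skipped",
                               mode, trip.route_id, trip.start_label)
                continue
            hours = minutes / 60.0
            doses = {}
            for fraction in SIZE_FRACTIONS:
                if mode == "bus" and measured_indoor and trip.indoor_mean is not None:
                    doses[fraction] = inhaled_dose(
                        trip.indoor_mean[fraction], 1.0, hours, ir_table[mode]
                    )
                else:
                    if trip.outdoor_mean is None:
                        raise ParameterError(
                            f"no outdoor means for {trip.route_id} {trip.start_label}"
                        )
                    doses[fraction] = inhaled_dose(
                        trip.outdoor_mean[fraction],
                        io_table[(mode, fraction)],
                        hours,
                        ir_table[mode],
                    )
            results.append(
                DoseResult(
                    route_id=trip.route_id,
                    start_label=trip.start_label,
                    mode=mode,
                    dose_pm25=doses["pm25"],
                    dose_pm10=doses["pm10"],
                )
            )
    return results


def dose_table_frame(results: Sequence[DoseResult]) -> pd.DataFrame:
    """Tabulate dose results, full precision (round only at presentation)."""
    return pd.DataFrame(
        {
            "route_id": [r.route_id for r in results],
            "start_label": [r.start_label for r in results],
            "mode": [r.mode for r in results],
            "dose_pm25": [r.dose_pm25 for r in results],
            "dose_pm10": [r.dose_pm10 for r in results],
        }
    )


def round_half_up(value: float, decimals: int = 1) -> float:
    """Presentation rounding (0.5 always away from zero), as in printed tables."""
    factor = 10.0**decimals
    return float(np.floor(abs(value) * factor + 0.5) / factor) * (1 if value >= 0 else -1)
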