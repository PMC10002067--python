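"""Data model, file I/O and configuration tables shared by every stage.

The package works on 1 Hz multi-channel readings from a mobile optical
particle counter node (PM2.5, PM10, temperature, relative humidity, optional
pressure and GPS fix), paired with reference-instrument series.  This module
defines the record types, reads/writes the on-disk CSV and GeoJSON formats,
and loads the configuration tables (inhalation rates, cabin indoor/outdoor
ratios, vehicle emission factors, correction settings) with literature
defaults baked in.

Conventions
-----------
* Timestamps are stored and compared in UTC; ISO-8601 inputs may carry an
  offset, which is converted on read (GPS time is UTC).
* A missing GPS fix is encoded as absent lat/lon; the record is kept for
  concentration statistics but skipped by map aggregation.
* Rows carrying the quality marker ``excluded`` (or failing the physical
  non-negativity invariant) are flagged, never silently dropped; every
  aggregation downstream honours the flag.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigError, FormatError, ParameterError, RowParseError

FLAG_OK = "ok"
FLAG_EXCLUDED = "excluded"

#: CSV columns that must be present in a sensor log.
SENSOR_LOG_REQUIRED = ("timestamp", "pm25", "pm10", "rh", "temperature")
SENSOR_LOG_OPTIONAL = ("lat", "lon", "pressure", "flag")

SIZE_FRACTIONS = ("pm25", "pm10")


@dataclass(frozen=True)
class SensorRecord:
    """One timestamped, optionally georeferenced multi-channel reading."""

    timestamp: datetime
    pm25: float
    pm10: float
    temperature: float
    rh: float
    lat: float | None = None
    lon: float | None = None
    pressure: float | None = None
    flag: str = FLAG_OK

    def __post_init__(self) -> None:
        if self.flag not in (FLAG_OK, FLAG_EXCLUDED):
            raise ParameterError(f"unknown quality flag {self.flag!r}")
        if self.flag == FLAG_OK and (self.pm25 < 0 or self.pm10 < 0):
            raise ParameterError("ok-flagged record with negative concentration")
        if not 0.0 <= self.rh <= 100.0:
            raise ParameterError(f"rh={self.rh} outside [0, 100] %")
        if self.lat is not None and not -90.0 <= self.lat <= 90.0:
            raise ParameterError(f"lat={self.lat} outside [-90, 90]")
        if self.lon is not None and not -180.0 <= self.lon <= 180.0:
            raise ParameterError(f"lon={self.lon} outside [-180, 180]")

    @property
    def has_fix(self) -> bool:
        return self.lat is not None and self.lon is not None


@dataclass(frozen=True)
class ReferenceRecord:
    """One reading from a reference instrument (dried inlet assumed)."""

    timestamp: datetime
    pm25: float
    pm10: float
    source: str = "beta-attenuation"

    def __post_init__(self) -> None:
        if self.pm25 < 0 or self.pm10 < 0:
            raise ParameterError("reference concentrations must be non-negative")


@dataclass(frozen=True)
class InhalationTable:
    """Mode-of-transport specific breathing rates, m^3 h^-1."""

    rates: Mapping[str, float]

    def __post_init__(self) -> None:
        for mode, rate in self.rates.items():
            if not rate > 0:
                raise ConfigError(f"inhalation rate for {mode!r} must be > 0, got {rate}")

    def __getitem__(self, mode: str) -> float:
        try:
            return self.rates[mode]
        except KeyError:
            raise ConfigError(
                f"no inhalation rate for mode {mode!r}; known: {sorted(self.rates)}"
            ) from None

    @property
    def modes(self) -> tuple[str, ...]:
        return tuple(self.rates)


@dataclass(frozen=True)
class IORatioTable:
    """Dimensionless cabin indoor/outdoor concentration ratios per size fraction."""

    ratios: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for mode, per_fraction in self.ratios.items():
            for fraction, value in per_fraction.items():
                if fraction not in SIZE_FRACTIONS:
                    raise ConfigError(f"unknown size fraction {fraction!r} for {mode!r}")
                if not value > 0:
                    raise ConfigError(f"I/O ratio for ({mode}, {fraction}) must be > 0")

    def __getitem__(self, key: tuple[str, str]) -> float:
        mode, fraction = key
        try:
            return self.ratios[mode][fraction]
        except KeyError:
            raise ConfigError(
                f"no I/O ratio for ({mode!r}, {fraction!r}); known modes: {sorted(self.ratios)}"
            ) from None


@dataclass(frozen=True)
class EmissionFactor:
    """Exhaust PM emission factor of one (vehicle, fuel, Euro standard), g km^-1."""

    vehicle: str
    fuel: str
    euro: str
    ef: float

    def __post_init__(self) -> None:
        if self.ef < 0:
            raise ConfigError(f"emission factor must be >= 0, got {self.ef}")
        if self.fuel == "electric" and self.ef != 0:
            raise ConfigError("electric vehicles must have a zero emission factor")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.vehicle, self.fuel, self.euro)


@dataclass(frozen=True)
class CorrectionSettings:
    """Knobs of the humidity/regression correction pipeline."""

    method: str = "auto"
    rho_w: float = 1.0
    rho_p: float = 1.65
    aw_cap: float = 0.95
    rh_bin_width: float = 2.0
    min_bin_count: int = 10
    tendency_margin: float = 0.1

    def __post_init__(self) -> None:
        if self.method not in ("kohler", "mlr", "auto"):
            raise ConfigError(f"correction method must be kohler|mlr|auto, got {self.method!r}")
        if not (self.rho_w > 0 and self.rho_p > 0):
            raise ConfigError("densities must be positive")
        if not 0 < self.aw_cap < 1:
            raise ConfigError("aw_cap must lie strictly between 0 and 1")


@dataclass(frozen=True)
class Config:
    inhalation: InhalationTable
    io_ratios: IORatioTable
    emission_factors: tuple[EmissionFactor, ...]
    occupancy: Mapping[str, int]
    correction: CorrectionSettings


# ---------------------------------------------------------------------------
# sensor / reference log CSV


def _parse_timestamp(raw: Any, line: int) -> datetime:
    try:
        ts = pd.Timestamp(raw)
        if ts is pd.NaT or pd.isna(ts):
            raise ValueError("empty timestamp")
    except (ValueError, TypeError) as exc:
        raise RowParseError(f"unparseable timestamp {raw!r}: {exc}", line=line) from exc
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return ts.tz_convert("UTC").to_pydatetime()


def _opt_float(value: Any) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_sensor_log(path: str | Path) -> list[SensorRecord]:
    """Read a 1 Hz sensor log CSV into validated, time-ordered records.

    The header must name at least ``timestamp, pm25, pm10, rh, temperature``
    (``lat, lon, pressure, flag`` optional).  Rows whose concentrations are
    negative, or which carry the ``excluded`` marker in the ``flag`` column,
    come back flagged rather than dropped.  Unparseable timestamps raise
    :class:`RowParseError` with the offending line number; a missing mandatory
    column raises :class:`FormatError` naming it.
    """
    frame = pd.read_csv(path, dtype={"flag": "string"})
    frame.columns = [c.strip().lower() for c in frame.columns]
    for column in SENSOR_LOG_REQUIRED:
        if column not in frame.columns:
            raise FormatError(f"sensor log {path} is missing mandatory column {column!r}")

    records: list[SensorRecord] = []
    for position, row in enumerate(frame.itertuples(index=False)):
        line = position + 2  # header is line 1
        ts = _parse_timestamp(getattr(row, "timestamp"), line)
        try:
            pm25 = float(getattr(row, "pm25"))
            pm10 = float(getattr(row, "pm10"))
            temperature = float(getattr(row, "temperature"))
            rh = float(getattr(row, "rh"))
        except (TypeError, ValueError) as exc:
            raise RowParseError(f"non-numeric field: {exc}", line=line) from exc
        flag = FLAG_OK
        raw_flag = getattr(row, "flag", None)
        if raw_flag is not None and not pd.isna(raw_flag) and str(raw_flag).strip():
            marker = str(raw_flag).strip().lower()
            flag = FLAG_EXCLUDED if marker == FLAG_EXCLUDED else FLAG_OK
        if pm25 < 0 or pm10 < 0:
            flag = FLAG_EXCLUDED  # physically impossible reading, keep but mark
        records.append(
            SensorRecord(
                timestamp=ts,
                pm25=pm25,
                pm10=pm10,
                temperature=temperature,
                rh=min(max(rh, 0.0), 100.0),
                lat=_opt_float(getattr(row, "lat", None)),
                lon=_opt_float(getattr(row, "lon", None)),
                pressure=_opt_float(getattr(row, "pressure", None)),
                flag=flag,
            )
        )
    records.sort(key=lambda r: r.timestamp)
    return records


def read_reference_log(path: str | Path) -> list[ReferenceRecord]:
    """Read a reference-instrument CSV (columns: timestamp, pm25, pm10[, source])."""
    frame = pd.read_csv(path)
    frame.columns = [c.strip().lower() for c in frame.columns]
    for column in ("timestamp", "pm25", "pm10"):
        if column not in frame.columns:
            raise FormatError(f"reference log {path} is missing mandatory column {column!r}")
    records = []
    for position, row in enumerate(frame.itertuples(index=False)):
        line = position + 2
        ts = _parse_timestamp(getattr(row, "timestamp"), line)
        records.append(
            ReferenceRecord(
                timestamp=ts,
                pm25=float(getattr(row, "pm25")),
                pm10=float(getattr(row, "pm10")),
                source=str(getattr(row, "source", "beta-attenuation")),
            )
        )
    records.sort(key=lambda r: r.timestamp)
    return records


def records_to_frame(records: Sequence[SensorRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame indexed by UTC timestamp."""
    if not records:
        return pd.DataFrame(
            columns=["pm25", "pm10", "temperature", "rh", "lat", "lon", "pressure", "flag"]
        )
    frame = pd.DataFrame([dataclasses.asdict(r) for r in records])
    frame["timestamp"] = pd.to_datetime(frame["timestamp"], utc=True)
    return frame.set_index("timestamp")


def write_sensor_log(records: Sequence[SensorRecord], path: str | Path) -> None:
    """Write records back to the sensor-log CSV schema (round-trip safe)."""
    frame = records_to_frame(records).reset_index()
    frame["timestamp"] = frame["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GeoJSON


def _validate_position(position: Sequence[float]) -> None:
    lon, lat = position[0], position[1]
    if not -180.0 <= lon <= 180.0 or not -90.0 <= lat <= 90.0:
        raise ParameterError(f"coordinate ({lon}, {lat}) out of range (lon,lat order)")


def _walk_positions(coordinates: Any) -> Iterable[Sequence[float]]:
    if coordinates and isinstance(coordinates[0], (int, float)):
        yield coordinates
    else:
        for part in coordinates:
            yield from _walk_positions(part)


def write_geojson(features: Iterable[Mapping[str, Any]], path: str | Path) -> None:
    """Write point/line/polygon features as an RFC 7946 FeatureCollection.

    ``features`` are mappings with ``geometry`` (type + lon,lat coordinates)
    and numeric ``properties``.  Coordinates are validated; properties are
    preserved at full double precision.
    """
    validated = []
    for feature in features:
        geometry = feature["geometry"]
        for position in _walk_positions(geometry["coordinates"]):
            _validate_position(position)
        validated.append(
            {
                "type": "Feature",
                "geometry": {"type": geometry["type"], "coordinates": geometry["coordinates"]},
                "properties": dict(feature.get("properties", {})),
            }
        )
    payload = {"type": "FeatureCollection", "features": validated}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_geojson(path: str | Path) -> dict[str, Any]:
    payload = json.loads(Path(path).read_text())
    if payload.get("type") != "FeatureCollection":
        raise FormatError(f"{path} is not a GeoJSON FeatureCollection")
    return payload


# ---------------------------------------------------------------------------
# configuration


def _default_config_mapping() -> dict[str, Any]:
    text = resources.files("commutair.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    merged = dict(base)
    for key, value in override.items():
        if key in merged and isinstance(merged[key], dict) and isinstance(value, Mapping):
            merged[key] = _deep_merge(merged[key], value)
        else:
            merged[key] = value
    return merged


def load_config(path: str | Path | None = None) -> Config:
    """Load the configuration tables, falling back to the packaged defaults.

    A user YAML file may override any subset of the sections
    ``inhalation_rates``, ``io_ratios``, ``emission_factors``, ``occupancy``
    and ``correction``; absent keys keep their default values.  Validation
    errors (negative rates, non-positive ratios) raise :class:`ConfigError`.
    """
    mapping = _default_config_mapping()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, Mapping):
            raise ConfigError(f"config file {path} must be a mapping of sections")
        if "emission_factors" in user:  # lists replace, mappings merge
            mapping["emission_factors"] = user["emission_factors"]
        mapping = _deep_merge(mapping, {k: v for k, v in user.items() if k != "emission_factors"})

    factors = tuple(
        EmissionFactor(
            vehicle=str(row["vehicle"]),
            fuel=str(row["fuel"]),
            euro=str(row["euro"]),
            ef=float(row["ef"]),
        )
        for row in mapping["emission_factors"]
    )
    return Config(
        inhalation=InhalationTable({str(k): float(v) for k, v in mapping["inhalation_rates"].items()}),
        io_ratios=IORatioTable(
            {
                str(mode): {str(f): float(v) for f, v in per.items()}
                for mode, per in mapping["io_ratios"].items()
            }
        ),
        emission_factors=factors,
        occupancy={str(k): int(v) for k, v in mapping["occupancy"].items()},
        correction=CorrectionSettings(**mapping["correction"]),
    )


def load_bus_trip_table() -> pd.DataFrame:
    """Packaged bus-campaign summary: per (route, start) indoor/outdoor mean
    and SD concentrations, two-way travel time and distance, meteorological
    ranges, and the exclusion marker for the period lost to a systematic
    sensor error."""
    with resources.files("commutair.data").joinpath("bus_trips.csv").open() as handle:
        frame = pd.read_csv(handle)
    frame["excluded"] = frame["excluded"].astype(bool)
    return frame


def utcnow() -> datetime:
    return datetime.now(timezone.utc)
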