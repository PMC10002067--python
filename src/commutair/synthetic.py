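"""Synthetic co-location and bus-trip data with the statistical structure the
calibration and exposure stages assume.

No public dataset accompanies the deployment this package models, so every
downstream stage is exercised on generated data whose structure mirrors the
field campaigns: a two-week co-location of an optical sensor against a
dried-inlet reference under strongly varying relative humidity, and paired
indoor/outdoor cabin traces along georeferenced bus routes.

Generating model
----------------
* Ambient concentrations follow an AR(1) process on the log scale
  (positivity guaranteed); PM10 = PM2.5 + an independent coarse log-AR(1)
  component, so the fine fraction never exceeds the total.
* Temperature and RH are 24 h sinusoids plus Gaussian jitter, RH clipped to
  [5, 95] %.
* The sensor response is ``gain * true * GF(RH; kappa, rho_p) + offset``
  plus multiplicative and/or additive Gaussian noise, truncated at zero —
  the forward model of the hygroscopic-growth correction, so correcting
  with the generating kappa inverts the confounding exactly in the
  noise-free limit.
* Cabin (indoor) series are the outdoor series scaled by a true
  indoor/outdoor ratio, plus Poisson-timed resuspension spikes that decay
  exponentially with a 60 s time constant.

All generators are pure functions of (scenario, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ParameterError
from .hygroscopic import KappaModel, growth_factor
from .sensor_io import SensorRecord

EARTH_RADIUS_M = 6_371_000.0
_EPOCH = datetime(2022, 6, 1, tzinfo=timezone.utc)


@dataclass(frozen=True)
class AmbientScenario:
    """Parameters of the synthetic ambient field (defaults: a 14-day urban
    background campaign sampled at 1-minute resolution)."""

    duration_h: float = 14 * 24.0
    step_s: float = 60.0
    pm25_base: float = 8.0       # µg m^-3, geometric level of the fine fraction
    pm10_base: float = 20.0      # µg m^-3, geometric level of PM10 (> pm25_base)
    log_ar1_rho: float = 0.98    # per-step persistence of log concentration
    log_sd: float = 0.5          # stationary SD of log concentration
    rh_mean: float = 55.0        # % — diurnal cycle spanning roughly 20-90 %
    rh_amplitude: float = 30.0
    rh_jitter_sd: float = 4.0
    t_mean: float = 20.0         # °C
    t_amplitude: float = 5.0
    t_jitter_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_h <= 0 or self.step_s <= 0:
            raise ParameterError("duration and step must be positive")
        if not 0 <= self.log_ar1_rho < 1:
            raise ParameterError("log_ar1_rho must lie in [0, 1)")
        if self.log_sd < 0:
            raise ParameterError("log_sd must be >= 0")
        if self.pm10_base <= self.pm25_base:
            raise ParameterError("pm10_base must exceed pm25_base")


@dataclass(frozen=True)
class SensorResponseModel:
    """Forward model of the optical sensor's systematic and random error."""

    gain: float = 1.0            # < 1 models the sensor's underestimation
    offset: float = 0.0          # µg m^-3
    noise_sd: float = 0.0        # additive Gaussian noise, µg m^-3
    noise_relative: float = 0.0  # multiplicative Gaussian noise fraction
    kappa_true: float = 0.0      # hygroscopicity driving RH confounding
    rho_p: float = 1.65          # g cm^-3

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ParameterError("gain must be positive")
        if self.noise_sd < 0 or self.noise_relative < 0:
            raise ParameterError("noise scales must be >= 0")
        if self.kappa_true < 0:
            raise ParameterError("kappa_true must be >= 0")


@dataclass(frozen=True)
class TripScenario:
    """A georeferenced two-way bus run with a cabin microenvironment."""

    polyline: Sequence[tuple[float, float]]  # (lat, lon) WGS84 vertices
    speed_kmh: float = 20.0
    io_true: dict = field(default_factory=lambda: {"pm25": 2.1, "pm10": 2.5})
    resuspension_spike_rate: float = 6.0   # events h^-1
    spike_magnitude: float = 20.0          # µg m^-3 added at event onset
    spike_tau_s: float = 60.0              # exponential decay constant
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.polyline) < 2:
            raise ParameterError("polyline needs at least 2 points")
        if self.speed_kmh <= 0:
            raise ParameterError("speed must be positive")
        if any(v <= 0 for v in self.io_true.values()):
            raise ParameterError("io_true ratios must be positive")


def _log_ar1(n: int, base: float, rho: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) on log scale around log(base)."""
    if sd == 0:
        return np.full(n, base)
    innov_sd = sd * math.sqrt(1.0 - rho * rho)
    eps = rng.normal(0.0, innov_sd, size=n)
    eps[0] = rng.normal(0.0, sd)  # stationary start
    z = lfilter([1.0], [1.0, -rho], eps)
    return base * np.exp(z)


def _diurnal(hours: np.ndarray, mean: float, amplitude: float, jitter_sd: float,
             rng: np.random.Generator, phase_h: float) -> np.ndarray:
    cycle = mean + amplitude * np.sin(2.0 * np.pi * (hours - phase_h) / 24.0)
    return cycle + rng.normal(0.0, jitter_sd, size=len(hours))


def simulate_ambient(scenario: AmbientScenario) -> pd.DataFrame:
    """Generate the true ambient field as a UTC-indexed DataFrame with columns
    ``pm25, pm10, temperature, rh``.

    Reproducible: the output is a deterministic function of the scenario
    (including its seed).  With ``log_sd = 0`` the concentration paths are
    constant at their base levels.
    """
    rng = np.random.default_rng(scenario.seed)
    n = int(round(scenario.duration_h * 3600.0 / scenario.step_s))
    if n < 2:
        raise ParameterError("scenario too short: fewer than 2 steps")
    hours = np.arange(n) * scenario.step_s / 3600.0

    pm25 = _log_ar1(n, scenario.pm25_base, scenario.log_ar1_rho, scenario.log_sd, rng)
    coarse_base = scenario.pm10_base - scenario.pm25_base
    coarse = _log_ar1(n, coarse_base, scenario.log_ar1_rho, scenario.log_sd, rng)
    pm10 = pm25 + coarse

    # RH peaks at night (anti-phase with temperature), as in typical diurnal cycles
    rh = _diurnal(hours, scenario.rh_mean, scenario.rh_amplitude,
                  scenario.rh_jitter_sd, rng, phase_h=14.0)
    rh = np.clip(rh, 5.0, 95.0)
    temperature = _diurnal(hours, scenario.t_mean, scenario.t_amplitude,
                           scenario.t_jitter_sd, rng, phase_h=2.0)

    index = pd.date_range(_EPOCH, periods=n, freq=pd.Timedelta(seconds=scenario.step_s), tz="UTC")
    return pd.DataFrame(
        {"pm25": pm25, "pm10": pm10, "temperature": temperature, "rh": rh}, index=index
    )


def simulate_sensor(
    pm_true: np.ndarray,
    rh: np.ndarray,
    response: SensorResponseModel,
    seed: int = 0,
) -> np.ndarray:
    """Push a true concentration series through the sensor's forward model."""
    pm_true = np.asarray(pm_true, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if pm_true.shape != rh.shape:
        raise ParameterError(f"misaligned series: {pm_true.shape} vs {rh.shape}")
    rng = np.random.default_rng(seed)
    gf = growth_factor(
        KappaModel(kappa=response.kappa_true, rho_p=response.rho_p), rh
    )
    reading = response.gain * pm_true * gf + response.offset
    if response.noise_relative > 0:
        reading = reading * (1.0 + rng.normal(0.0, response.noise_relative, size=len(reading)))
    if response.noise_sd > 0:
        reading = reading + rng.normal(0.0, response.noise_sd, size=len(reading))
    return np.maximum(reading, 0.0)


# ---------------------------------------------------------------------------
# trips


def _path_metrics(polyline: Sequence[tuple[float, float]]) -> tuple[np.ndarray, float]:
    """Cumulative along-path distance (m) at each vertex, and the total."""
    lats = np.radians([p[0] for p in polyline])
    lons = np.radians([p[1] for p in polyline])
    lat0 = float(np.mean(lats))
    x = EARTH_RADIUS_M * math.cos(lat0) * lons
    y = EARTH_RADIUS_M * lats
    seg = np.hypot(np.diff(x), np.diff(y))
    cumulative = np.concatenate([[0.0], np.cumsum(seg)])
    return cumulative, float(cumulative[-1])


def _spike_profile(n: int, rate_per_h: float, magnitude: float, tau_s: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Superposed exponentially decaying pulses at Poisson-distributed onsets."""
    profile = np.zeros(n)
    if rate_per_h <= 0 or magnitude <= 0:
        return profile
    n_events = rng.poisson(rate_per_h * n / 3600.0)
    t = np.arange(n, dtype=float)
    for onset in np.sort(rng.uniform(0, n, size=n_events)):
        active = t >= onset
        profile[active] += magnitude * np.exp(-(t[active] - onset) / tau_s)
    return profile


def simulate_trip(
    trip: TripScenario, ambient: pd.DataFrame
) -> tuple[list[SensorRecord], list[SensorRecord], dict]:
    """Sample the ambient field along a trip at 1 s, producing paired
    outdoor/cabin sensor streams and a ground-truth summary.

    The cabin stream is ``io_true × outdoor`` plus resuspension spikes; the
    truth dict records the generating ratios and the realised stream means.
    """
    cumulative, total_m = _path_metrics(trip.polyline)
    if total_m <= 0:
        raise ParameterError("polyline has zero length")
    duration_s = total_m / (trip.speed_kmh / 3.6)
    n = max(int(round(duration_s)), 2)
    rng = np.random.default_rng(trip.seed)

    # position by linear interpolation of the vertices over along-path distance
    travelled = np.linspace(0.0, total_m, n)
    lats = np.interp(travelled, cumulative, [p[0] for p in trip.polyline])
    lons = np.interp(travelled, cumulative, [p[1] for p in trip.polyline])

    epoch = (ambient.index - ambient.index[0]).total_seconds().to_numpy()
    seconds = np.arange(n, dtype=float)
    outdoor = {
        column: np.interp(seconds, epoch, ambient[column].to_numpy())
        for column in ("pm25", "pm10", "temperature", "rh")
    }

    spikes = _spike_profile(n, trip.resuspension_spike_rate, trip.spike_magnitude,
                            trip.spike_tau_s, rng)
    indoor = {
        fraction: trip.io_true[fraction] * outdoor[fraction] + spikes
        for fraction in ("pm25", "pm10")
    }

    start = ambient.index[0].to_pydatetime()
    outdoor_records, indoor_records = [], []
    for i in range(n):
        ts = start + timedelta(seconds=float(seconds[i]))
        common = dict(
            timestamp=ts,
            temperature=float(outdoor["temperature"][i]),
            rh=float(np.clip(outdoor["rh"][i], 0.0, 100.0)),
            lat=float(lats[i]),
            lon=float(lons[i]),
        )
        outdoor_records.append(
            SensorRecord(pm25=float(outdoor["pm25"][i]), pm10=float(outdoor["pm10"][i]), **common)
        )
        indoor_records.append(
            SensorRecord(pm25=float(indoor["pm25"][i]), pm10=float(indoor["pm10"][i]), **common)
        )

    truth = {
        "io_true": dict(trip.io_true),
        "duration_s": duration_s,
        "distance_m": total_m,
        "outdoor_mean": {f: float(np.mean(outdoor[f])) for f in ("pm25", "pm10")},
        "indoor_mean": {f: float(np.mean(indoor[f])) for f in ("pm25", "pm10")},
        "n_samples": n,
    }
    return outdoor_records, indoor_records, truth
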