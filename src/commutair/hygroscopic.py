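"""Humidity correction of optical PM readings via single-parameter hygroscopic
growth (the κ-Köhler framework).

Optical particle counters sample ambient, humid air: hygroscopic particles
swell with water uptake and scatter as larger, heavier particles, so raw
readings overshoot the dry mass a reference instrument (dried inlet) reports.
The wet/dry mass ratio is modelled as

    m / m0 = 1 + (rho_w / rho_p) * kappa / (1 / a_w - 1)

with water activity a_w = RH/100 (capped just below saturation), water
density rho_w, dry-particle density rho_p, and a single hygroscopicity
parameter kappa.  kappa is estimated as the slope of the humidogram — the
sensor/reference ratio binned over RH — and the correction divides the wet
reading by the modelled growth factor.

The module also provides the diagnostic used to choose between this
correction and a plain multilinear regression: the κ-form is only worth
applying when the humidogram shows a clear exponential-looking rise with RH.

Estimator interface: :class:`KappaHumidityCorrector` follows the sklearn
fit/transform contract; the module-level functions are the procedural
surface over the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InsufficientDataError, ParameterError

#: defaults: water density, assumed dry-particle density (g cm^-3),
#: water-activity cap avoiding the 1/a_w - 1 -> 0 singularity at saturation.
RHO_W_DEFAULT = 1.0
RHO_P_DEFAULT = 1.65
AW_CAP_DEFAULT = 0.95


@dataclass(frozen=True)
class KappaModel:
    """Hygroscopicity parameter and the densities entering the growth factor."""

    kappa: float
    rho_w: float = RHO_W_DEFAULT
    rho_p: float = RHO_P_DEFAULT
    aw_cap: float = AW_CAP_DEFAULT
    diagnostics: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ParameterError(f"kappa must be >= 0, got {self.kappa}")
        if not (self.rho_w > 0 and self.rho_p > 0):
            raise ParameterError("densities must be positive")
        if not 0 < self.aw_cap < 1:
            raise ParameterError("aw_cap must lie strictly in (0, 1)")


@dataclass(frozen=True)
class Humidogram:
    """Sensor/reference concentration ratio binned over relative humidity."""

    rh_bin_centers: np.ndarray
    mean_ratio: np.ndarray
    counts: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        if np.any(self.mean_ratio <= 0):
            raise ParameterError("humidogram ratios must be positive")


def _kappa_basis(rh: np.ndarray, rho_w: float, rho_p: float, aw_cap: float) -> np.ndarray:
    """x such that GF = 1 + kappa * x; x -> 0 in the dry limit."""
    aw = np.clip(np.asarray(rh, dtype=float) / 100.0, 0.0, aw_cap)
    with np.errstate(divide="ignore", over="ignore"):
        x = (rho_w / rho_p) / (1.0 / aw - 1.0)
    # 1/aw overflows for denormal aw; the dry limit is 0 either way
    return np.where(np.isfinite(x) & (aw > 0), x, 0.0)


def growth_factor(model: KappaModel, rh: Any) -> Any:
    """Wet/dry mass ratio at relative humidity ``rh`` (percent).

    Vectorised; the dry limit RH -> 0 gives exactly 1, and the result is
    monotone non-decreasing in RH for any kappa >= 0.
    """
    rh_arr = np.asarray(rh, dtype=float)
    if np.any(rh_arr < 0) or np.any(rh_arr > 100):
        raise ParameterError("rh must lie in [0, 100] %")
    gf = 1.0 + model.kappa * _kappa_basis(rh_arr, model.rho_w, model.rho_p, model.aw_cap)
    return float(gf) if np.isscalar(rh) else gf


def correct_humidity(model: KappaModel, wet: Any, rh: Any) -> np.ndarray:
    """Divide wet (sensor) readings by the modelled growth factor."""
    wet_arr = np.asarray(wet, dtype=float)
    rh_arr = np.asarray(rh, dtype=float)
    if wet_arr.shape != rh_arr.shape:
        raise ParameterError(
            f"wet and rh series are misaligned: {wet_arr.shape} vs {rh_arr.shape}"
        )
    return wet_arr / growth_factor(model, rh_arr)


def build_humidogram(
    sensor: Any,
    reference: Any,
    rh: Any,
    bin_width: float = 2.0,
    min_count: int = 10,
) -> Humidogram:
    """Bin the sensor/reference ratio over RH.

    Only samples with strictly positive reference (ratio defined) enter;
    bins retaining fewer than ``min_count`` samples are dropped.  Fewer than
    three surviving bins leave nothing to fit an RH dependence to and raise
    :class:`InsufficientDataError`.
    """
    sensor = np.asarray(sensor, dtype=float)
    reference = np.asarray(reference, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if not (sensor.shape == reference.shape == rh.shape):
        raise ParameterError("sensor, reference and rh series must be aligned")
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")

    usable = (reference > 0) & (sensor > 0) & np.isfinite(rh)
    ratio = sensor[usable] / reference[usable]
    rh_use = rh[usable]

    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    idx = np.clip(np.digitize(rh_use, edges) - 1, 0, len(edges) - 2)
    centers, means, counts = [], [], []
    for b in np.unique(idx):
        members = ratio[idx == b]
        if len(members) >= min_count:
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            means.append(float(np.mean(members)))
            counts.append(len(members))
    if len(centers) < 3:
        raise InsufficientDataError(
            f"only {len(centers)} humidogram bins have >= {min_count} samples; need >= 3"
        )
    return Humidogram(
        rh_bin_centers=np.asarray(centers),
        mean_ratio=np.asarray(means),
        counts=np.asarray(counts),
        bin_width=bin_width,
    )


def fit_kappa(
    humidogram: Humidogram,
    rho_w: float = RHO_W_DEFAULT,
    rho_p: float = RHO_P_DEFAULT,
    aw_cap: float = AW_CAP_DEFAULT,
) -> KappaModel:
    """Estimate kappa by least squares of the binned ratios on the κ-form.

    Since GF - 1 is linear in kappa, the estimate is the closed-form
    through-origin OLS slope of (ratio - 1) on the basis
    (rho_w/rho_p)/(1/a_w - 1) at the bin centers.  A negative unconstrained
    estimate (no positive RH dependence) is floored at 0 and kept in the
    diagnostics.
    """
    x = _kappa_basis(humidogram.rh_bin_centers, rho_w, rho_p, aw_cap)
    y = humidogram.mean_ratio - 1.0
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise InsufficientDataError("humidogram bins are all at RH 0; kappa undefined")
    kappa_raw = float(np.dot(x, y) / denom)
    kappa = max(kappa_raw, 0.0)

    fitted = 1.0 + kappa * x
    ss_res = float(np.sum((humidogram.mean_ratio - fitted) ** 2))
    ss_tot = float(np.sum((humidogram.mean_ratio - np.mean(humidogram.mean_ratio)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return KappaModel(
        kappa=kappa,
        rho_w=rho_w,
        rho_p=rho_p,
        aw_cap=aw_cap,
        diagnostics={"kappa_raw": kappa_raw, "r_squared": r2, "n_bins": len(x)},
    )


def exponential_tendency(
    humidogram: Humidogram,
    rho_w: float = RHO_W_DEFAULT,
    rho_p: float = RHO_P_DEFAULT,
    aw_cap: float = AW_CAP_DEFAULT,
    margin: float = 0.1,
) -> dict[str, Any]:
    """Advise between the κ correction and multilinear regression.

    The κ-form is recommended only when its fit explains clearly more of the
    humidogram's variance than a flat (RH-independent) ratio — i.e. its R²,
    computed about the bin-mean, exceeds ``margin``.  A straight-line fit in
    RH is reported for reference but does not drive the recommendation.  The
    advice is never auto-applied.
    """
    model = fit_kappa(humidogram, rho_w=rho_w, rho_p=rho_p, aw_cap=aw_cap)
    r2_kappa = model.diagnostics["r_squared"]
    if model.kappa == 0.0:
        r2_kappa = 0.0  # flat fit: no exponential tendency by construction

    # straight line in RH, for the diagnostics only
    coeffs = np.polyfit(humidogram.rh_bin_centers, humidogram.mean_ratio, 1)
    linear_fit = np.polyval(coeffs, humidogram.rh_bin_centers)
    ss_tot = float(np.sum((humidogram.mean_ratio - np.mean(humidogram.mean_ratio)) ** 2))
    r2_linear = (
        1.0 - float(np.sum((humidogram.mean_ratio - linear_fit) ** 2)) / ss_tot
        if ss_tot > 0
        else 0.0
    )

    recommend = "kohler" if r2_kappa > margin else "mlr"
    return {
        "recommend": recommend,
        "r2_kappa": r2_kappa,
        "r2_flat": 0.0,
        "r2_linear": r2_linear,
        "kappa": model.kappa,
        "margin": margin,
    }


class KappaHumidityCorrector(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: learn kappa from co-location data, then dry
    out sensor readings.

    Parameters
    ----------
    rho_w, rho_p : float
        Water and dry-particle densities, g cm^-3.
    aw_cap : float
        Upper cap on water activity (protects the near-saturation pole).
    bin_width : float
        Humidogram RH bin width, percent.
    min_count : int
        Minimum samples for a humidogram bin to be retained.

    ``fit(X, y)`` expects ``X`` of shape (n, 2) with columns (sensor reading,
    RH in percent) and ``y`` the aligned reference series; ``transform(X)``
    returns the humidity-corrected (dry-equivalent) readings.

    Attributes
    ----------
    model_ : KappaModel
        Fitted hygroscopicity model.
    humidogram_ : Humidogram
        The binned ratio curve kappa was estimated from.
    """

    def __init__(
        self,
        rho_w: float = RHO_W_DEFAULT,
        rho_p: float = RHO_P_DEFAULT,
        aw_cap: float = AW_CAP_DEFAULT,
        bin_width: float = 2.0,
        min_count: int = 10,
    ):
        self.rho_w = rho_w
        self.rho_p = rho_p
        self.aw_cap = aw_cap
        self.bin_width = bin_width
        self.min_count = min_count

    def _split(self, X: Any) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ParameterError("X must have two columns: (sensor, rh)")
        return X[:, 0], X[:, 1]

    def fit(self, X: Any, y: Any) -> "KappaHumidityCorrector":
        sensor, rh = self._split(X)
        reference = np.asarray(y, dtype=float)
        self.humidogram_ = build_humidogram(
            sensor, reference, rh, bin_width=self.bin_width, min_count=self.min_count
        )
        self.model_ = fit_kappa(
            self.humidogram_, rho_w=self.rho_w, rho_p=self.rho_p, aw_cap=self.aw_cap
        )
        self.tendency_ = exponential_tendency(
            self.humidogram_, rho_w=self.rho_w, rho_p=self.rho_p, aw_cap=self.aw_cap
        )
        return self

    def transform(self, X: Any) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise ParameterError("corrector is not fitted")
        sensor, rh = self._split(X)
        return correct_humidity(self.model_, sensor, rh)
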