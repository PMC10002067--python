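"""Regression calibration of the optical sensor against reference instruments.

Four ordinary-least-squares forms correct the sensor, written with the
*sensor* as the response (the instrument being modelled) and the reference
concentration — optionally with temperature and relative humidity — as
regressors:

    SLR:       PM_sensor = a * PM_ref + b
    MLR_T:     PM_sensor = c * PM_ref + d * T + e
    MLR_RH:    PM_sensor = f * PM_ref + g * RH + h
    MLR_T_RH:  PM_sensor = i * PM_ref + j * T + k * RH + l

Correction inverts the fitted equation for PM_ref rather than refitting
reference-on-sensor (the two differ under noise; the inverted orientation is
the one the equations define).  Negative corrected values are floored at 0
and counted in the log.

The same machinery at 24 h resolution provides the gravimetric correction
chain used to traceably correct optical reference instruments against
filter-weighing measurements.

:class:`SensorCalibrator` is the sklearn-style estimator (fit/predict,
``get_params``); the module functions wrap it for procedural use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import FitError, ParameterError, SingularityError

logger = logging.getLogger(__name__)

#: regression form -> (coefficient names, covariates beyond the reference)
FORMS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "slr": (("a", "b"), ()),
    "mlr_t": (("c", "d", "e"), ("temperature",)),
    "mlr_rh": (("f", "g", "h"), ("rh",)),
    "mlr_t_rh": (("i", "j", "k", "l"), ("temperature", "rh")),
}

#: leading coefficient magnitudes below this are treated as non-invertible
LEAD_COEF_TOL = 1e-12


@dataclass(frozen=True)
class ComparisonStats:
    """OLS slope/intercept/R² of y on x — the agreement diagnostic."""

    r_squared: float
    slope: float
    intercept: float
    n: int


@dataclass(frozen=True)
class CalibrationFit:
    """Fitted coefficients of one regression form plus agreement diagnostics."""

    form: str
    coefficients: Mapping[str, float]
    n_points: int
    diagnostics: ComparisonStats
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names, covariates = FORMS[self.form]
        if tuple(self.coefficients) != names:
            raise ParameterError(
                f"form {self.form!r} needs coefficients {names}, got {tuple(self.coefficients)}"
            )
        if self.n_points < len(names) + 1:
            raise FitError(f"{self.n_points} points cannot constrain {len(names)} coefficients")

    @property
    def lead(self) -> float:
        """Coefficient multiplying the reference concentration."""
        return next(iter(self.coefficients.values()))

    @property
    def intercept(self) -> float:
        return list(self.coefficients.values())[-1]

    def covariate_coefficients(self) -> dict[str, float]:
        values = list(self.coefficients.values())[1:-1]
        return dict(zip(FORMS[self.form][1], values))


def comparison_stats(x: Any, y: Any) -> ComparisonStats:
    """OLS of y on x: slope, intercept and coefficient of determination."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError(f"misaligned series: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise FitError(f"need at least 3 points, got {len(x)}")
    if np.ptp(x) == 0:
        raise SingularityError("x series is constant; slope undefined")
    result = stats.linregress(x, y)
    return ComparisonStats(
        r_squared=float(result.rvalue**2),
        slope=float(result.slope),
        intercept=float(result.intercept),
        n=len(x),
    )


def _design_matrix(
    reference: np.ndarray, covariates: dict[str, np.ndarray], names: tuple[str, ...]
) -> np.ndarray:
    columns = [reference]
    for name in names:
        if name not in covariates or covariates[name] is None:
            raise ParameterError(f"form requires the {name!r} series")
        columns.append(np.asarray(covariates[name], dtype=float))
    columns.append(np.ones_like(reference))
    return np.column_stack(columns)


def fit_calibration(
    sensor: Any,
    reference: Any,
    temperature: Any | None = None,
    rh: Any | None = None,
    form: str = "slr",
) -> CalibrationFit:
    """Fit one of the four regression forms by OLS, sensor as response.

    Series must be aligned (co-averaged upstream if they came from
    instruments with different native resolutions).  Raises
    :class:`SingularityError` naming any zero-variance regressor and
    :class:`FitError` when there are too few points.
    """
    if form not in FORMS:
        raise ParameterError(f"unknown form {form!r}; choose from {sorted(FORMS)}")
    names, covariate_names = FORMS[form]
    sensor = np.asarray(sensor, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if sensor.shape != reference.shape:
        raise ParameterError("sensor and reference series are misaligned")
    n = len(sensor)
    if n < len(names) + 1:
        raise FitError(f"need at least {len(names) + 1} points for form {form!r}, got {n}")

    covariates = {"temperature": temperature, "rh": rh}
    X = _design_matrix(reference, covariates, covariate_names)
    for label, column in zip(("reference",) + covariate_names, X.T[:-1]):
        if np.ptp(column) == 0:
            raise SingularityError(f"regressor {label!r} has zero variance")

    beta, *_ = np.linalg.lstsq(X, sensor, rcond=None)
    return CalibrationFit(
        form=form,
        coefficients=dict(zip(names, (float(b) for b in beta))),
        n_points=n,
        diagnostics=comparison_stats(reference, sensor),
        covariates=covariate_names,
    )


def apply_calibration(
    fit: CalibrationFit,
    sensor: Any,
    temperature: Any | None = None,
    rh: Any | None = None,
) -> np.ndarray:
    """Invert the fitted equation for the reference concentration.

    E.g. for the full form: (PM_sensor - j*T - k*RH - l) / i.  Negative
    results are floored at 0; the count of floored samples is logged.
    """
    if abs(fit.lead) < LEAD_COEF_TOL:
        raise SingularityError(
            f"leading coefficient {fit.lead!r} is within tolerance of 0; equation not invertible"
        )
    sensor = np.asarray(sensor, dtype=float)
    adjusted = sensor - fit.intercept
    supplied = {"temperature": temperature, "rh": rh}
    for name, coef in fit.covariate_coefficients().items():
        if supplied[name] is None:
            raise ParameterError(f"fit of form {fit.form!r} requires the {name!r} series")
        adjusted = adjusted - coef * np.asarray(supplied[name], dtype=float)
    corrected = adjusted / fit.lead
    n_floored = int(np.sum(corrected < 0))
    if n_floored:
        logger.info("apply_calibration floored %d negative corrected values at 0", n_floored)
    return np.maximum(corrected, 0.0)


def co_average(
    left: pd.Series, right: pd.Series, freq: str = "1min", min_count: int = 1
) -> tuple[pd.Series, pd.Series]:
    """Average two timestamp-indexed series onto common time bins.

    Bins are paired when both series contribute at least ``min_count``
    samples; each sample lands in the nearest bin (within half a bin width,
    by construction of the resampling grid).
    """
    lbin = left.resample(freq).mean()
    rbin = right.resample(freq).mean()
    common = lbin.dropna().index.intersection(rbin.dropna().index)
    return lbin.loc[common], rbin.loc[common]


def gravimetric_correction(
    optical_daily: pd.Series, gravimetric_daily: pd.Series
) -> tuple[CalibrationFit, pd.Series]:
    """Correct 24 h optical means against gravimetric filter measurements.

    Both inputs are indexed by date and must pair exactly; unpaired dates
    raise :class:`FitError` listing them.  Returns the SLR fit (optical as
    response, same machinery as :func:`fit_calibration`) and the corrected
    optical series.
    """
    unpaired = optical_daily.index.symmetric_difference(gravimetric_daily.index)
    if len(unpaired):
        raise FitError(f"unpaired dates between optical and gravimetric series: {list(unpaired)}")
    fit = fit_calibration(optical_daily.to_numpy(), gravimetric_daily.to_numpy(), form="slr")
    corrected = pd.Series(
        apply_calibration(fit, optical_daily.to_numpy()),
        index=optical_daily.index,
        name="corrected",
    )
    return fit, corrected


class SensorCalibrator(RegressorMixin, BaseEstimator):
    """Sklearn-style estimator wrapping the regression correction.

    Parameters
    ----------
    form : {"slr", "mlr_t", "mlr_rh", "mlr_t_rh"}
        Which regression form to fit.

    ``fit(X, y)`` takes ``X`` of shape (n, k) whose columns are the sensor
    reading followed by the covariates the form requires, in the order
    (sensor[, temperature][, rh]); ``y`` is the aligned reference series.
    ``predict(X)`` returns the corrected (reference-scale) concentrations by
    algebraic inversion of the fitted equation.

    Attributes
    ----------
    fit_ : CalibrationFit
        Coefficients and diagnostics of the fitted form.
    n_floored_ : int
        Number of negative corrected values floored at 0 by the last
        ``predict`` call.
    """

    def __init__(self, form: str = "slr"):
        self.form = form

    def _columns(self, X: Any) -> tuple[np.ndarray, dict[str, np.ndarray | None]]:
        if self.form not in FORMS:
            raise ParameterError(f"unknown form {self.form!r}; choose from {sorted(FORMS)}")
        covariate_names = FORMS[self.form][1]
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        expected = 1 + len(covariate_names)
        if X.shape[1] != expected:
            raise ParameterError(
                f"form {self.form!r} expects {expected} columns (sensor"
                + "".join(f", {c}" for c in covariate_names)
                + f"), got {X.shape[1]}"
            )
        covariates: dict[str, np.ndarray | None] = {"temperature": None, "rh": None}
        for j, name in enumerate(covariate_names, start=1):
            covariates[name] = X[:, j]
        return X[:, 0], covariates

    def fit(self, X: Any, y: Any) -> "SensorCalibrator":
        sensor, covariates = self._columns(X)
        self.fit_ = fit_calibration(
            sensor,
            np.asarray(y, dtype=float),
            temperature=covariates["temperature"],
            rh=covariates["rh"],
            form=self.form,
        )
        self.n_floored_ = 0
        return self

    def predict(self, X: Any) -> np.ndarray:
        if not hasattr(self, "fit_"):
            raise ParameterError("calibrator is not fitted")
        sensor, covariates = self._columns(X)
        raw_lead = self.fit_.lead
        adjusted = sensor - self.fit_.intercept
        for name, coef in self.fit_.covariate_coefficients().items():
            adjusted = adjusted - coef * covariates[name]
        corrected = adjusted / raw_lead if abs(raw_lead) >= LEAD_COEF_TOL else None
        if corrected is None:
            raise SingularityError("leading coefficient within tolerance of 0")
        self.n_floored_ = int(np.sum(corrected < 0))
        return np.maximum(corrected, 0.0)
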