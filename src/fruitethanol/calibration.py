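"""Calibration-series regression and inverse prediction.

Each field assay (MOS headspace sensor, portable gas chromatograph,
dichromate colorimetry) is calibrated against a serial-dilution standard
series of known ethanol concentration (% w/w).  The known concentration —
or its natural log for the MOS sensor, whose response is log-linear — is
regressed on the raw instrument response by ordinary least squares, and the
fitted line is applied directly to sample responses to predict ethanol
concentration.  Diagnostics are the adjusted R^2 of the regression and the
mean absolute error (MAE) of the back-transformed predictions against the
known standard concentrations.

Negative predicted concentrations are physically meaningless and are
clamped to zero after dilution scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm

from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidArgumentError,
    MethodMismatchError,
)

Method = Literal["MOS", "GC", "CR2"]
Transform = Literal["identity", "log_concentration"]

#: transform used when fitting each assay's standards
METHOD_TRANSFORMS: dict[str, Transform] = {
    "MOS": "log_concentration",
    "GC": "identity",
    "CR2": "identity",
}

MIN_STANDARDS = 3


@dataclass(frozen=True)
class CalibrationSeries:
    """A standard series: known % w/w levels paired with raw responses.

    ``role`` records whether the series bracketed a sample batch before or
    after it was run ("pre"/"post") or pools several series ("pooled").
    """

    method: Method
    standards: tuple[tuple[float, float], ...]
    label: str = ""
    role: Literal["pre", "post", "pooled"] = "pooled"

    def __post_init__(self) -> None:
        std = tuple((float(k), float(r)) for k, r in self.standards)
        object.__setattr__(self, "standards", std)
        if self.method not in METHOD_TRANSFORMS:
            raise InvalidArgumentError(f"unknown method {self.method!r}")
        if self.method == "MOS" and any(k <= 0 for k, _ in std):
            raise InvalidArgumentError(
                "MOS standards require known_pct > 0 (log transform undefined at 0)"
            )

    @property
    def known(self) -> np.ndarray:
        return np.array([k for k, _ in self.standards], dtype=float)

    @property
    def responses(self) -> np.ndarray:
        return np.array([r for _, r in self.standards], dtype=float)

    def __len__(self) -> int:
        return len(self.standards)


@dataclass(frozen=True)
class CalibrationFit:
    """Fitted inverse-prediction line concentration = f(response).

    ``slope``/``intercept`` act on the raw response and yield concentration
    (identity transform) or log concentration (log_concentration transform,
    back-transformed with exp).  ``mae`` is in % w/w on the concentration
    scale; ``adj_r2`` refers to the regression on the fitted scale.
    """

    method: Method
    slope: float
    intercept: float
    transform: Transform
    adj_r2: float = float("nan")
    mae: float = float("nan")
    n_standards: int = 0

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "log_concentration"):
            raise InvalidArgumentError(f"unknown transform {self.transform!r}")


def fit_calibration(series: CalibrationSeries) -> CalibrationFit:
    """OLS fit of (possibly log-transformed) known concentration on response.

    Raises
    ------
    InsufficientDataError
        Fewer than three standards.
    DegenerateDesignError
        All responses identical (no slope identifiable).
    """
    if len(series) < MIN_STANDARDS:
        raise InsufficientDataError(
            f"calibration needs >= {MIN_STANDARDS} standards, got {len(series)}"
        )
    x = series.responses
    if np.ptp(x) == 0.0:
        raise DegenerateDesignError("all standard responses identical")
    transform = METHOD_TRANSFORMS[series.method]
    y = np.log(series.known) if transform == "log_concentration" else series.known

    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = float(model.params[0]), float(model.params[1])
    n = len(series)
    # adjusted R^2 degenerates for n == 2 regressors + intercept edge cases
    adj_r2 = float(model.rsquared_adj) if n - 2 > 0 else float("nan")

    fit = CalibrationFit(
        method=series.method,
        slope=slope,
        intercept=intercept,
        transform=transform,
        adj_r2=adj_r2,
        n_standards=n,
    )
    mae = calibration_mae(fit, series)
    return CalibrationFit(
        method=series.method,
        slope=slope,
        intercept=intercept,
        transform=transform,
        adj_r2=adj_r2,
        mae=mae,
        n_standards=n,
    )


def predict_concentration(
    fit: CalibrationFit, response: float, dilution_factor: float = 1.0
) -> float:
    """Invert a raw response to whole-sample ethanol in % w/w.

    Identity transform: ``max(0, slope*response + intercept) * dilution``;
    log transform: ``exp(slope*response + intercept) * dilution``.  Negative
    values are rounded up to zero (after dilution scaling, which is
    equivalent for dilution_factor >= 1).
    """
    if dilution_factor < 1:
        raise InvalidArgumentError("dilution_factor must be >= 1")
    linear = fit.slope * response + fit.intercept
    if fit.transform == "log_concentration":
        return math.exp(linear) * dilution_factor
    return max(0.0, linear * dilution_factor)


def adjusted_r2(
    observed: Sequence[float], predicted: Sequence[float], n_params: int = 1
) -> float:
    """Adjusted coefficient of determination.

    ``1 - (1 - R^2) * (n - 1) / (n - n_params - 1)`` with R^2 the ordinary
    coefficient of determination of ``predicted`` against ``observed``.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise InvalidArgumentError("observed and predicted lengths differ")
    n = obs.size
    if n - n_params - 1 <= 0:
        raise DegenerateDesignError(
            f"adjusted R^2 undefined for n={n} with {n_params} parameters"
        )
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateDesignError("observed values have zero variance")
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def calibration_mae(fit: CalibrationFit, series: CalibrationSeries) -> float:
    """Mean |known - back-transformed prediction| over the standards, % w/w."""
    if len(series) == 0:
        raise InsufficientDataError("empty calibration series")
    if METHOD_TRANSFORMS[series.method] != fit.transform:
        raise MethodMismatchError(
            f"fit transform {fit.transform!r} incompatible with {series.method} series"
        )
    preds = np.array(
        [predict_concentration(fit, r, 1.0) for r in series.responses]
    )
    return float(np.mean(np.abs(series.known - preds)))


def bracket_fit(
    pre_series: CalibrationSeries, post_series: CalibrationSeries
) -> CalibrationFit:
    """Pool the standards of a pre/post bracketing pair into one fit.

    Standard series are run immediately before and after each batch of
    fruit samples to absorb instrument drift; the pooled OLS line splits the
    drift between them.
    """
    if pre_series.method != post_series.method:
        raise MethodMismatchError(
            f"cannot pool {pre_series.method} with {post_series.method} series"
        )
    pooled = CalibrationSeries(
        method=pre_series.method,
        standards=pre_series.standards + post_series.standards,
        label=f"{pre_series.label}+{post_series.label}".strip("+"),
        role="pooled",
    )
    return fit_calibration(pooled)
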