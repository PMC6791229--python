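"""The GM(1,1) family of grey forecasting models.

Grey models address forecasting from very small, strictly positive samples.
The raw series x(0) is smoothed by the first-order accumulated generating
operation (AGO) into x(1); a two-parameter linear difference (or
differential) form is then estimated by ordinary least squares, the
accumulated series is predicted forward, and first differencing (inverse
AGO) restores predictions to the original scale.

Five variants are provided, differing in the estimation form and the
prediction rule:

=========  =========================================  ==============================
model      estimation form (k = 2..n)                 prediction of x(1)
=========  =========================================  ==============================
EGM        x0(k) = -a z1(k) + b                       (x0(1) - b/a) e^(-a(k-1)) + b/a
EDGM       x0(k) = -a z1(k) + b                       x1(k) = ((1-a/2) x1(k-1) + b) / (1+a/2)
ODGM       x0(k) = -a x1(k) + b                       x1(k) = (x1(k-1) + b) / (1+a)
DGM        x1(k) = beta1 x1(k-1) + beta2              same recursion
Verhulst   x0(k) = -a z1(k) + b z1(k)^2               logistic time response (below)
=========  =========================================  ==============================

where z1(k) = (x1(k) + x1(k-1)) / 2 is the mean-generated background value.
All five anchor the first fitted value at x(0)(1) exactly.  The Verhulst
variant treats the *raw* series as the S-curve state x(1) (its first
difference plays the role of x(0)) and reports the logistic time response
directly, without differencing.
"""

from __future__ import annotations

import json
from abc import abstractmethod
from dataclasses import dataclass
from typing import ClassVar

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .series import AnnualSeries, DatasetSplit

__all__ = [
    "ago",
    "iago",
    "background",
    "EvenGreyModel",
    "EvenDifferenceGreyModel",
    "OriginalDifferenceGreyModel",
    "DiscreteGreyModel",
    "GreyVerhulst",
    "MODEL_ORDER",
    "MODEL_REGISTRY",
    "fit_grey",
    "fit_all",
    "fitted_table",
]

_A_TOL = 1e-12  # below this the development coefficient is treated as zero


class GreyModelError(ValueError):
    """Raised for degenerate or rank-deficient grey-model fits."""


def ago(x0: np.ndarray) -> np.ndarray:
    """First-order accumulated generating operation: x1(k) = sum_{i<=k} x0(i)."""
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 <= 0):
        raise GreyModelError("AGO requires strictly positive input")
    return np.cumsum(x0)

def iago(x1: np.ndarray, anchor: float) -> np.ndarray:
    """Inverse AGO: first differences of ``x1`` with the first value replaced
    by ``anchor`` (the preserved initial observation x(0)(1))."""
    x1 = np.asarray(x1, dtype=float)
    out = np.empty_like(x1)
    out[0] = anchor
    if len(x1) > 1:
        out[1:] = np.diff(x1)
    return out

def background(x1: np.ndarray) -> np.ndarray:
    """Mean-generated background values z1(k) = (x1(k) + x1(k-1))/2, k = 2..n."""
    x1 = np.asarray(x1, dtype=float)
    if len(x1) < 2:
        raise GreyModelError("background values need at least two points")
    return 0.5 * (x1[1:] + x1[:-1])


def _ols(design: np.ndarray, response: np.ndarray) -> np.ndarray:
    """Least squares via SVD-backed lstsq; raises on rank deficiency."""
    coef, _, rank, _ = np.linalg.lstsq(design, response, rcond=None)
    if rank < design.shape[1]:
        raise GreyModelError("singular normal equations (collinear regressors)")
    return coef


class GreyModel(BaseEstimator):
    """Base class for the GM(1,1) family.

    These are univariate forecasters: ``fit`` consumes the training series
    only (there is no exogenous design matrix) and ``forecast`` extends the
    model's recursion or time response beyond the training window.

    Fitted attributes
    -----------------
    x0_ : training values; x1_ : accumulated training series
    train_years_ : calendar years of the training window
    fitted_ : restored fitted values over the training window
    """

    model_id: ClassVar[str]

    def fit(self, y, years=None) -> "GreyModel":
        if isinstance(y, AnnualSeries):
            years = y.years
            y = y.values
        x0 = np.asarray(y, dtype=float)
        if x0.ndim != 1 or len(x0) < 4:
            raise GreyModelError("grey models need a 1-D series of length >= 4")
        if np.any(x0 <= 0):
            raise GreyModelError("grey models require strictly positive values")
        self.x0_ = x0
        self.x1_ = ago(x0)
        self.n_ = len(x0)
        self.train_years_ = (
            np.asarray(years, dtype=int) if years is not None else np.arange(1, self.n_ + 1)
        )
        self._estimate()
        self.fitted_ = self._restored(self.n_)[: self.n_]
        return self

    def forecast(self, horizon: int) -> np.ndarray:
        """Restored predictions for the ``horizon`` steps after the window."""
        if horizon < 1:
            raise GreyModelError("horizon must be >= 1")
        return self._restored(self.n_ + horizon)[self.n_ :]

    @abstractmethod
    def _estimate(self) -> None:
        """Estimate parameters from x0_/x1_ by OLS."""

    @abstractmethod
    def _restored(self, upto: int) -> np.ndarray:
        """Restored (original-scale) model values for k = 1..upto."""

    # -- reporting ---------------------------------------------------------
    def params_dict(self) -> dict[str, float]:
        keys = ("a_", "b_", "beta1_", "beta2_")
        return {k.rstrip("_"): float(getattr(self, k)) for k in keys if hasattr(self, k)}

    def to_dict(self, horizon: int = 0) -> dict:
        doc = {
            "model_id": self.model_id,
            "params": self.params_dict(),
            "years": self.train_years_.tolist(),
            "fitted": self.fitted_.tolist(),
        }
        if horizon:
            doc["forecast"] = self.forecast(horizon).tolist()
        return doc

    def to_json(self, horizon: int = 0, **kwargs) -> str:
        return json.dumps(self.to_dict(horizon), **kwargs)


class _EvenFormMixin:
    """OLS estimation of (a, b) from x0(k) = -a z1(k) + b.

    A constant series makes the even form unidentifiable (any line through
    the single (z, x0) point fits); the zero-slope limit a = 0, b = x0(1)
    is used, which reproduces the constant exactly in both prediction rules.
    """

    def _estimate(self) -> None:
        if np.ptp(self.x0_) == 0.0:
            self.a_, self.b_ = 0.0, float(self.x0_[0])
            return
        z1 = background(self.x1_)
        design = np.column_stack([-z1, np.ones_like(z1)])
        self.a_, self.b_ = _ols(design, self.x0_[1:])


class EvenGreyModel(_EvenFormMixin, GreyModel):
    """EGM: even-form estimation, continuous (whitening-equation) prediction.

    The restored values grow geometrically with ratio e^(-a) from k = 2 on.
    For |a| below tolerance the analytic limit x1(k) = x0(1) + b (k-1) is
    used, so a constant series is fitted exactly rather than failing.
    """

    model_id = "EGM"

    def _restored(self, upto: int) -> np.ndarray:
        k = np.arange(1, upto + 1, dtype=float)
        if abs(self.a_) < _A_TOL:
            x1hat = self.x0_[0] + self.b_ * (k - 1)
        else:
            c = self.x0_[0] - self.b_ / self.a_
            x1hat = c * np.exp(-self.a_ * (k - 1)) + self.b_ / self.a_
        return iago(x1hat, self.x0_[0])


class _RecursiveRestoreMixin:
    """Restoration by running a linear recursion on x1 and differencing."""

    def _restored(self, upto: int) -> np.ndarray:
        x1hat = np.empty(upto)
        x1hat[0] = self.x0_[0]
        for k in range(1, upto):
            x1hat[k] = self._step(x1hat[k - 1])
        return iago(x1hat, self.x0_[0])


class EvenDifferenceGreyModel(_EvenFormMixin, _RecursiveRestoreMixin, GreyModel):
    """EDGM: even-form estimation, discrete recursion prediction.

    Restored growth ratio (1 - a/2) / (1 + a/2) from k = 2 on; exact on
    homogeneous exponential sequences.
    """

    model_id = "EDGM"

    def _estimate(self) -> None:
        super()._estimate()
        if abs(1.0 + self.a_ / 2.0) < _A_TOL:
            raise GreyModelError("degenerate EDGM recursion: 1 + a/2 ~ 0")

    def _step(self, prev: float) -> float:
        return ((1.0 - self.a_ / 2.0) * prev + self.b_) / (1.0 + self.a_ / 2.0)


class OriginalDifferenceGreyModel(_RecursiveRestoreMixin, GreyModel):
    """ODGM: estimation and prediction both from x0(k) = -a x1(k) + b.

    Restored growth ratio 1 / (1 + a); exact on homogeneous exponentials.
    """

    model_id = "ODGM"

    def _estimate(self) -> None:
        design = np.column_stack([-self.x1_[1:], np.ones(self.n_ - 1)])
        self.a_, self.b_ = _ols(design, self.x0_[1:])
        if abs(1.0 + self.a_) < _A_TOL:
            raise GreyModelError("degenerate ODGM recursion: 1 + a ~ 0")

    def _step(self, prev: float) -> float:
        return (prev + self.b_) / (1.0 + self.a_)


class DiscreteGreyModel(_RecursiveRestoreMixin, GreyModel):
    """DGM: linear recursion x1(k) = beta1 x1(k-1) + beta2 on the
    accumulated series.  Restored growth ratio beta1; exact on homogeneous
    exponentials (beta1 recovers the growth ratio r)."""

    model_id = "DGM"

    def _estimate(self) -> None:
        design = np.column_stack([self.x1_[:-1], np.ones(self.n_ - 1)])
        self.beta1_, self.beta2_ = _ols(design, self.x1_[1:])

    def _step(self, prev: float) -> float:
        return self.beta1_ * prev + self.beta2_


class GreyVerhulst(GreyModel):
    """Grey Verhulst model for S-shaped (saturating) series.

    The raw series itself is the logistic state x(1); its first difference
    x(0) is regressed on the background value and its square,
    x0(k) = -a z1(k) + b z1(k)^2, and the fitted values are the logistic
    time response

        x1(k) = a x1(1) / (b x1(1) + (a - b x1(1)) e^(a (k-1))),

    reported directly (no differencing).  The carrying capacity is a/b.

    Out-of-sample predictions advance the time response one extra index
    step (forecast step h evaluates k = n + h + 1).  This convention is
    what the tabulated reference predictions this package is validated
    against use, and it is kept so that downstream hybrid features match
    those reference values; see docs/methods.md.
    """

    model_id = "VERHULST"

    def _estimate(self) -> None:
        v1 = self.x0_  # raw series as logistic state
        v0 = np.diff(v1)
        z = background(v1)
        design = np.column_stack([-z, z**2])
        self.a_, self.b_ = _ols(design, v0)

    @property
    def capacity_(self) -> float:
        return self.a_ / self.b_

    def _time_response(self, k: np.ndarray) -> np.ndarray:
        x1 = self.x0_[0]
        if abs(self.b_) < _A_TOL * abs(self.a_):
            return x1 * np.exp(-self.a_ * (k - 1))  # b -> 0 exponential limit
        denom = self.b_ * x1 + (self.a_ - self.b_ * x1) * np.exp(self.a_ * (k - 1))
        if np.any(denom == 0):
            raise GreyModelError("degenerate Verhulst time response")
        return self.a_ * x1 / denom

    def _restored(self, upto: int) -> np.ndarray:
        k = np.arange(1, upto + 1, dtype=float)
        k = np.where(k > self.n_, k + 1.0, k)  # shifted out-of-sample convention
        return self._time_response(k)


MODEL_ORDER: tuple[str, ...] = ("EGM", "EDGM", "ODGM", "DGM", "VERHULST")

MODEL_REGISTRY: dict[str, type[GreyModel]] = {
    "EGM": EvenGreyModel,
    "EDGM": EvenDifferenceGreyModel,
    "ODGM": OriginalDifferenceGreyModel,
    "DGM": DiscreteGreyModel,
    "VERHULST": GreyVerhulst,
}


def fit_grey(model_id: str, series: AnnualSeries | np.ndarray) -> GreyModel:
    """Fit one grey model (by id, case-insensitive) to a training series."""
    key = model_id.upper()
    if key not in MODEL_REGISTRY:
        raise GreyModelError(f"unknown grey model {model_id!r}")
    return MODEL_REGISTRY[key]().fit(series)


def fit_all(
    series: AnnualSeries | np.ndarray,
) -> tuple[dict[str, GreyModel], dict[str, Exception]]:
    """Fit all five grey models; per-model failures are collected, not fatal.

    Returns ``(fits, errors)`` where ``errors`` maps a model id to the
    exception raised for it (e.g. Verhulst on a constant series).
    """
    fits: dict[str, GreyModel] = {}
    errors: dict[str, Exception] = {}
    for mid in MODEL_ORDER:
        try:
            fits[mid] = fit_grey(mid, series)
        except GreyModelError as exc:  # rank errors, degeneracies
            errors[mid] = exc
    return fits, errors


def fitted_table(
    fits: dict[str, GreyModel],
    split: DatasetSplit,
    round_to_int: bool = False,
) -> pd.DataFrame:
    """Year-by-year actual values and per-model fitted/forecast values.

    One row per year of the full series (train then test); model columns in
    the fixed order EGM, EDGM, ODGM, DGM, VERHULST (fitted values over the
    training window, forecasts over the test window).
    """
    horizon = len(split.test)
    years = np.concatenate([split.train.years, split.test.years])
    actual = np.concatenate([split.train.values, split.test.values])
    table = pd.DataFrame({"year": years, "actual": actual})
    for mid in MODEL_ORDER:
        if mid not in fits:
            continue
        fit = fits[mid]
        table[mid] = np.concatenate([fit.fitted_, fit.forecast(horizon)])
    if round_to_int:
        for col in table.columns.drop("year"):
            table[col] = np.floor(table[col] + 0.5).astype(int)
    return table
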