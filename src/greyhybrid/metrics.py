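"""Forecast accuracy statistics.

Errors are signed as e_t = A_t - F_t (actual minus forecast), so a model
that over-predicts has negative mean error and mean percentage error.
Percentage statistics divide by the actual values, which must therefore be
strictly positive.  Training-window reports include every training point —
including the first one, which all grey models fit with zero error by
construction.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import DatasetSplit

__all__ = ["AccuracyReport", "accuracy", "accuracy_table", "round_half_up"]


@dataclass(frozen=True)
class AccuracyReport:
    """Mean error, RMSE, MAE, mean percentage error and MAPE for one
    (actual, predicted) pairing.  ME/RMSE/MAE are in count units; MPE and
    MAPE are percentages."""

    me: float
    rmse: float
    mae: float
    mpe: float
    mape: float
    n: int

    def as_row(self, decimals: int | None = 2) -> dict[str, float]:
        vals = {"ME": self.me, "RMSE": self.rmse, "MAE": self.mae, "MPE": self.mpe, "MAPE": self.mape}
        if decimals is not None:
            vals = {k: round_half_up(v, decimals) for k, v in vals.items()}
        return vals


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal round-half-up (halves away from zero), reporting layer only."""
    q = decimal.Decimal(10) ** -decimals
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def accuracy(actual, predicted) -> AccuracyReport:
    """Compute the five accuracy statistics for one prediction set."""
    a = np.asarray(actual, dtype=float)
    f = np.asarray(predicted, dtype=float)
    if a.shape != f.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("actual and predicted must be equally long 1-D arrays")
    if np.any(a <= 0):
        raise ValueError("percentage errors require strictly positive actual values")
    e = a - f
    return AccuracyReport(
        me=float(e.mean()),
        rmse=float(np.sqrt((e**2).mean())),
        mae=float(np.abs(e).mean()),
        mpe=float(100.0 * (e / a).mean()),
        mape=float(100.0 * (np.abs(e) / a).mean()),
        n=len(a),
    )


def _predictions(obj, split: DatasetSplit) -> tuple[np.ndarray, np.ndarray]:
    """Extract (train, test) predictions from a grey fit or hybrid result."""
    if hasattr(obj, "fitted_") and hasattr(obj, "forecast"):
        return np.asarray(obj.fitted_), np.asarray(obj.forecast(len(split.test)))
    if hasattr(obj, "train_predictions") and hasattr(obj, "test_predictions"):
        return np.asarray(obj.train_predictions), np.asarray(obj.test_predictions)
    raise TypeError(f"cannot extract predictions from {type(obj).__name__}")


def accuracy_table(
    fits_or_results: dict[str, object],
    split: DatasetSplit,
    decimals: int | None = 2,
) -> pd.DataFrame:
    """One training row and one testing row per model, keyed
    ``<label>_training`` / ``<label>_testing``.

    Accepts fitted grey models (fitted_/forecast) or hybrid results
    (train_predictions/test_predictions).  Values are rounded half-up to
    ``decimals`` places at this reporting layer only; pass ``None`` for
    unrounded output.
    """
    rows = []
    for label, obj in fits_or_results.items():
        train_pred, test_pred = _predictions(obj, split)
        if len(test_pred) != len(split.test):
            raise ValueError(f"{label}: missing forecasts for test years")
        for group, actual, pred in (
            ("training", split.train.values, train_pred),
            ("testing", split.test.values, test_pred),
        ):
            rep = accuracy(actual, pred)
            rows.append({"model": f"{label}_{group}", **rep.as_row(decimals)})
    return pd.DataFrame(rows).set_index("model")
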