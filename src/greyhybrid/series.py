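"""Annual incidence series: container, CSV I/O, normalization, chronological
splitting and synthetic-series generation.

The modelling substrate is a short, strictly annual, strictly positive count
series ``x(0) = (x(0)(1), ..., x(0)(n))``.  Grey models assume equally spaced
observations and divide by the raw values when computing percentage errors,
so both invariants (consecutive years, positivity) are enforced at
construction time rather than deep inside the fitting code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


class SeriesValidationError(ValueError):
    """Raised when a series violates the annual-count invariants."""


@dataclass(frozen=True)
class AnnualSeries:
    """An ordered annual count series with optional per-year region counts.

    Parameters
    ----------
    years : array-like of int
        Calendar years, strictly consecutive (no gaps).
    values : array-like of float
        Strictly positive case counts (stored as floats; a normalized
        series holds per-region rates here).
    region_counts : array-like of int, optional
        Number of reporting regions per year, used by
        :func:`normalize_per_region`.
    """

    years: np.ndarray
    values: np.ndarray
    region_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.ndim != 1 or values.ndim != 1 or len(years) != len(values):
            raise SeriesValidationError("years and values must be 1-D and equally long")
        if len(years) == 0:
            raise SeriesValidationError("empty series")
        dup = years[:-1][np.diff(years) == 0]
        if dup.size:
            raise SeriesValidationError(f"duplicate year {int(dup[0])}")
        gaps = np.nonzero(np.diff(years) != 1)[0]
        if gaps.size:
            missing = int(years[gaps[0]]) + 1
            raise SeriesValidationError(f"gap in years: missing {missing}")
        if not np.all(values > 0):
            bad = int(years[np.argmax(values <= 0)])
            raise SeriesValidationError(f"non-positive count in year {bad}")
        if self.region_counts is not None:
            rc = np.asarray(self.region_counts, dtype=float)
            if rc.shape != years.shape:
                raise SeriesValidationError("region_counts length mismatch")
            if not np.all(rc > 0):
                raise SeriesValidationError("region_counts must be positive")
            object.__setattr__(self, "region_counts", rc)

    def __len__(self) -> int:
        return len(self.years)

    def slice(self, start: int, stop: int) -> "AnnualSeries":
        rc = None if self.region_counts is None else self.region_counts[start:stop]
        return AnnualSeries(self.years[start:stop], self.values[start:stop], rc)

    def to_frame(self) -> pd.DataFrame:
        d = {"year": self.years, "count": self.values}
        if self.region_counts is not None:
            d["regions"] = self.region_counts
        return pd.DataFrame(d)


@dataclass(frozen=True)
class DatasetSplit:
    """A chronological train/test partition of an :class:`AnnualSeries`."""

    train: AnnualSeries
    test: AnnualSeries

    def __post_init__(self) -> None:
        if self.train.years[-1] + 1 != self.test.years[0]:
            raise SeriesValidationError("train years must immediately precede test years")


def load_series(
    path: str | Path,
    year_col: str = "year",
    count_col: str = "count",
    regions_col: str = "regions",
) -> AnnualSeries:
    """Read a ``year,count[,regions]`` CSV (header row required) into an
    :class:`AnnualSeries`, sorting rows by year and enforcing the invariants."""
    df = pd.read_csv(path)
    for col in (year_col, count_col):
        if col not in df.columns:
            raise SeriesValidationError(f"missing column {col!r} in {path}")
    df = df.sort_values(year_col)
    rc = df[regions_col].to_numpy() if regions_col in df.columns else None
    return AnnualSeries(df[year_col].to_numpy(), df[count_col].to_numpy(), rc)


def save_series(series: AnnualSeries, path: str | Path) -> None:
    """Write the fixed ``year,count[,regions]`` CSV dialect.

    Integer-valued counts are written without a decimal point so that
    load -> save -> load round-trips byte-exactly for count data.
    """
    df = series.to_frame()
    for col in ("count", "regions"):
        if col in df.columns and np.allclose(df[col], np.round(df[col])):
            df[col] = df[col].astype(int)
    df.to_csv(path, index=False)


def load_china() -> AnnualSeries:
    """The packaged China occupational-disease series, 2005-2017.

    Thirteen annual nationwide case counts with the number of reporting
    provinces per year (29 in 2006, 31 in 2015-2017, 30 otherwise).
    """
    from importlib.resources import files

    with files("greyhybrid.data").joinpath("china_occupational_2005_2017.csv").open() as fh:
        return load_series(fh)


def normalize_per_region(series: AnnualSeries) -> AnnualSeries:
    """Divide each count by that year's number of reporting regions.

    The region counts are retained on the result so the transformation is
    invertible via :func:`denormalize_per_region`.
    """
    if series.region_counts is None:
        raise SeriesValidationError("normalize_per_region requires region_counts")
    return AnnualSeries(series.years, series.values / series.region_counts, series.region_counts)


def denormalize_per_region(series: AnnualSeries) -> AnnualSeries:
    if series.region_counts is None:
        raise SeriesValidationError("denormalize_per_region requires region_counts")
    return AnnualSeries(series.years, series.values * series.region_counts, series.region_counts)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_series(series: AnnualSeries, train_fraction: float = 0.75) -> DatasetSplit:
    """Chronological train/test split.

    The train size is ``round_half_up(n * train_fraction)``, clamped so the
    training window keeps at least 3 observations and the test window at
    least 1.  The default fraction of 0.75 puts the first ten of thirteen
    years (2005-2014) in training and the last three (2015-2017) in test,
    the split used throughout the packaged example.
    """
    n = len(series)
    if n < 4:
        raise SeriesValidationError("need at least 4 observations to split")
    if not 0.0 < train_fraction < 1.0:
        raise SeriesValidationError("train_fraction must lie in (0, 1)")
    n_train = min(max(_round_half_up(n * train_fraction), 3), n - 1)
    return DatasetSplit(series.slice(0, n_train), series.slice(n_train, n))


def concat_series(a: AnnualSeries, b: AnnualSeries) -> AnnualSeries:
    rc = None
    if a.region_counts is not None and b.region_counts is not None:
        rc = np.concatenate([a.region_counts, b.region_counts])
    return AnnualSeries(
        np.concatenate([a.years, b.years]), np.concatenate([a.values, b.values]), rc
    )


_GENERATOR_DEFAULTS: dict[str, dict[str, float]] = {
    # q: initial level, r: annual growth ratio
    "geometric": {"q": 100.0, "r": 1.15},
    # capacity: saturation level, x1: initial level, growth: logistic rate
    "logistic": {"capacity": 1000.0, "x1": 50.0, "growth": 0.5},
    # linear trend plus a bounded sine term; amplitude < base keeps positivity
    "oscillating": {"base": 100.0, "trend": 5.0, "amplitude": 20.0, "period": 6.0},
}


def generate_series(
    kind: str,
    n: int,
    seed: int,
    noise_sd: float = 0.0,
    params: Mapping[str, float] | None = None,
    start_year: int = 2005,
) -> AnnualSeries:
    """Generate a synthetic annual series.

    ``kind`` is one of ``geometric`` (``x(k) = q * r**(k-1)``, the sequence
    class the difference-form grey models reproduce exactly), ``logistic``
    (discrete S-curve approaching ``capacity``, the Verhulst regime) or
    ``oscillating`` (trend plus bounded periodic term, never crossing zero).
    Multiplicative log-normal noise with log-scale standard deviation
    ``noise_sd`` is applied afterwards; ``noise_sd=0`` returns the exact
    deterministic sequence.  Identical seeds give identical series.
    """
    if n < 4:
        raise SeriesValidationError("n must be at least 4")
    if kind not in _GENERATOR_DEFAULTS:
        raise SeriesValidationError(f"unknown kind {kind!r}")
    p = dict(_GENERATOR_DEFAULTS[kind])
    p.update(params or {})
    k = np.arange(1, n + 1, dtype=float)
    if kind == "geometric":
        if p["q"] <= 0 or p["r"] <= 0:
            raise SeriesValidationError("geometric requires q > 0 and r > 0")
        values = p["q"] * p["r"] ** (k - 1)
    elif kind == "logistic":
        c, x1, g = p["capacity"], p["x1"], p["growth"]
        if not (0 < x1 < c):
            raise SeriesValidationError("logistic requires 0 < x1 < capacity")
        values = c / (1.0 + (c / x1 - 1.0) * np.exp(-g * (k - 1)))
    else:  # oscillating
        values = p["base"] + p["trend"] * (k - 1) + p["amplitude"] * np.sin(2 * np.pi * k / p["period"])
        if np.any(values <= 0):
            raise SeriesValidationError("oscillating parameters produce non-positive values")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values * np.exp(rng.normal(0.0, noise_sd, size=n))
    return AnnualSeries(start_year + np.arange(n), values)
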