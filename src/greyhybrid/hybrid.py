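"""Two-stage grey / machine-learning hybrid forecasting.

Stage one fits the five grey models to the training window; their restored
fitted values (training years) and forecasts (test years) form a per-year
feature matrix in the fixed column order EGM, EDGM, ODGM, DGM, VERHULST.
Stage two fits a conventional regressor (KNN, SVR, random forest, gradient
boosting, or a small sigmoid network) mapping those features to the actual
counts, and is evaluated chronologically on the held-out years.  Model
selection ranks candidates by testing MAPE, breaking ties by testing RMSE.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .ann import SigmoidNeuralRegressor
from .grey import MODEL_ORDER, GreyModel
from .metrics import AccuracyReport, accuracy, round_half_up
from .series import DatasetSplit

__all__ = [
    "HybridDataset",
    "RegressorSpec",
    "HybridResult",
    "build_features",
    "make_regressor",
    "train_predict",
    "subset_search",
    "select_best",
    "default_specs",
    "results_table",
]

log = logging.getLogger(__name__)

DEFAULT_SEED = 20190929

#: Stated hyperparameters for the five second-stage families.
FAMILY_DEFAULTS: dict[str, dict] = {
    "knn": {"k": 2, "weights": "uniform"},
    "svr": {"kernel": "radial", "cost": 1.0, "epsilon": 0.1, "degree": 3, "coef0": 0.0},
    "rf": {"mtry": 1, "ntree": 30},
    "gbm": {
        "nrounds": 100,
        "eta": 0.1,
        "gamma": 0.5,
        "max_depth": 3,
        "subsample": 0.5,
        "colsample_bytree": 1.0,
        "min_child_weight": 1,
    },
    "ann": {"size": 5, "decay": 1e-8, "max_iterations": 10000, "convergence_tol": 1e-8},
}

_SVR_KERNELS = {"linear": "linear", "polynomial": "poly", "radial": "rbf", "sigmoid": "sigmoid"}


@dataclass(frozen=True)
class HybridDataset:
    """Per-year grey-model feature vectors with actual counts as labels."""

    years: np.ndarray
    features: np.ndarray  # (n_years, n_subset_models)
    labels: np.ndarray
    is_train: np.ndarray  # boolean per year
    feature_names: tuple[str, ...]

    @property
    def train_X(self) -> np.ndarray:
        return self.features[self.is_train]

    @property
    def train_y(self) -> np.ndarray:
        return self.labels[self.is_train]

    @property
    def test_X(self) -> np.ndarray:
        return self.features[~self.is_train]

    @property
    def test_y(self) -> np.ndarray:
        return self.labels[~self.is_train]


@dataclass(frozen=True)
class RegressorSpec:
    """A second-stage regressor family plus hyperparameters.

    ``hyperparameters`` is merged over the family defaults, which are the
    stated reference configuration (knn k=2; rf mtry=1, ntree=30; gbm
    nrounds=100, eta=0.1, gamma=0.5, max_depth=3, subsample=0.5; ann
    size=5, decay=1e-8, 10000 iterations, tolerance 1e-8).
    """

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = DEFAULT_SEED
    restarts: int = 50  # ann only
    label: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILY_DEFAULTS:
            raise ValueError(f"unknown regressor family {self.family!r}")
        merged = {**FAMILY_DEFAULTS[self.family], **self.hyperparameters}
        object.__setattr__(self, "hyperparameters", merged)
        if self.label is None:
            tag = {
                "knn": lambda h: f"knn[k={h['k']},{h['weights']}]",
                "svr": lambda h: f"svr[{h['kernel']}]",
                "rf": lambda h: f"rf[mtry={h['mtry']},ntree={h['ntree']}]",
                "gbm": lambda h: "gbm",
                "ann": lambda h: f"ann[size={h['size']}]",
            }[self.family](self.hyperparameters)
            object.__setattr__(self, "label", tag)


@dataclass(frozen=True)
class HybridResult:
    """Fitted second-stage model outputs over both windows with accuracy."""

    spec: RegressorSpec
    feature_subset: tuple[str, ...]
    years: np.ndarray
    train_predictions: np.ndarray
    test_predictions: np.ndarray
    train_accuracy: AccuracyReport
    test_accuracy: AccuracyReport
    converged: bool = True


def build_features(
    fits: dict[str, GreyModel],
    split: DatasetSplit,
    subset: tuple[str, ...] | None = None,
) -> HybridDataset:
    """Assemble the hybrid dataset from fitted grey models.

    One row per year of the full series; feature columns are the restored
    fitted values (training window) and forecasts (test window) of the
    models in ``subset`` (default: all available, in the fixed order).
    Labels are the actual counts; test labels are used only for evaluation.
    """
    if subset is None:
        subset = tuple(m for m in MODEL_ORDER if m in fits)
    else:
        subset = tuple(s.upper() for s in subset)
    if not subset:
        raise ValueError("empty grey-model subset")
    missing = [m for m in subset if m not in fits]
    if missing:
        raise ValueError(f"no grey fit for {missing}")
    horizon = len(split.test)
    cols = []
    for mid in subset:
        fit = fits[mid]
        if len(fit.fitted_) != len(split.train):
            raise ValueError(f"{mid}: fitted values do not cover the training years")
        cols.append(np.concatenate([fit.fitted_, fit.forecast(horizon)]))
    years = np.concatenate([split.train.years, split.test.years])
    labels = np.concatenate([split.train.values, split.test.values])
    is_train = np.arange(len(years)) < len(split.train)
    return HybridDataset(years, np.column_stack(cols), labels, is_train, subset)


def make_regressor(spec: RegressorSpec, n_features: int):
    """Instantiate the sklearn-style estimator for a spec.

    KNN and SVR follow the conventional small-sample setups: KNN on raw
    features with uniform or inverse-distance weights; SVR with
    standardized features and labels (the customary preprocessing of the
    reference SVR implementation), cost 1, epsilon 0.1 and kernel
    coefficient 1/n_features.
    """
    h = spec.hyperparameters
    if spec.family == "knn":
        weights = {"uniform": "uniform", "inverse": "distance", "distance": "distance"}.get(
            h["weights"]
        )
        if weights is None:
            raise ValueError(f"unknown knn weighting {h['weights']!r}")
        return KNeighborsRegressor(n_neighbors=h["k"], weights=weights)
    if spec.family == "svr":
        if h["kernel"] not in _SVR_KERNELS:
            raise ValueError(f"unknown svr kernel {h['kernel']!r}")
        svr = SVR(
            kernel=_SVR_KERNELS[h["kernel"]],
            C=h["cost"],
            epsilon=h["epsilon"],
            degree=h["degree"],
            coef0=h["coef0"],
            gamma=h.get("gamma", 1.0 / n_features),
        )
        return TransformedTargetRegressor(
            regressor=make_pipeline(StandardScaler(), svr), transformer=StandardScaler()
        )
    if spec.family == "rf":
        return RandomForestRegressor(
            n_estimators=h["ntree"], max_features=h["mtry"], random_state=spec.seed
        )
    if spec.family == "gbm":
        from xgboost import XGBRegressor

        return XGBRegressor(
            n_estimators=h["nrounds"],
            learning_rate=h["eta"],
            gamma=h["gamma"],
            max_depth=h["max_depth"],
            subsample=h["subsample"],
            colsample_bytree=h["colsample_bytree"],
            min_child_weight=h["min_child_weight"],
            objective="reg:squarederror",
            random_state=spec.seed,
            n_jobs=1,
        )
    # ann
    return SigmoidNeuralRegressor(
        hidden_units=h["size"],
        decay=h["decay"],
        max_iter=h["max_iterations"],
        tol=h["convergence_tol"],
        restarts=spec.restarts,
        random_state=spec.seed,
    )


def train_predict(spec: RegressorSpec, data: HybridDataset) -> HybridResult:
    """Fit one second-stage regressor and evaluate on both windows.

    Training-window predictions are in-sample: the query year is part of
    the fitted model (its own neighbourhood for KNN, the fitted ensemble
    for trees), so inverse-distance KNN reproduces its labels exactly.
    """
    if data.train_X.shape[0] < 3:
        raise ValueError("need at least 3 training rows")
    if not np.all(np.isfinite(data.features)):
        raise ValueError("non-finite features")
    est = make_regressor(spec, data.features.shape[1])
    est.fit(data.train_X, data.train_y)
    train_pred = np.asarray(est.predict(data.train_X), dtype=float)
    test_pred = np.asarray(est.predict(data.test_X), dtype=float)
    converged = bool(getattr(est, "converged_", True))
    if not converged:
        log.warning("%s: optimizer did not converge within the iteration cap", spec.label)
    return HybridResult(
        spec=spec,
        feature_subset=data.feature_names,
        years=data.years,
        train_predictions=train_pred,
        test_predictions=test_pred,
        train_accuracy=accuracy(data.train_y, train_pred),
        test_accuracy=accuracy(data.test_y, test_pred),
        converged=converged,
    )


def _rank_key(item: tuple[tuple[str, ...], HybridResult]):
    subset, res = item
    return (res.test_accuracy.mape, res.test_accuracy.rmse, -len(subset), subset)


def subset_search(
    fits: dict[str, GreyModel],
    split: DatasetSplit,
    spec: RegressorSpec,
) -> tuple[list[tuple[tuple[str, ...], HybridResult]], dict[tuple[str, ...], Exception]]:
    """Evaluate one regressor spec on every non-empty grey-feature subset.

    With all five grey models available this enumerates the 31 candidate
    subsets.  Returns the results ranked by testing MAPE (ties: testing
    RMSE, then larger subsets first, then lexicographic), plus a map of
    per-subset failures.
    """
    ids = tuple(m for m in MODEL_ORDER if m in fits)
    results: list[tuple[tuple[str, ...], HybridResult]] = []
    failures: dict[tuple[str, ...], Exception] = {}
    for size in range(1, len(ids) + 1):
        for subset in itertools.combinations(ids, size):
            try:
                data = build_features(fits, split, subset)
                results.append((subset, train_predict(spec, data)))
            except Exception as exc:  # recorded, not fatal
                failures[subset] = exc
                log.warning("subset %s failed: %s", subset, exc)
    results.sort(key=_rank_key)
    return results, failures


def select_best(results: list[HybridResult]) -> HybridResult:
    """Minimum testing MAPE; ties broken by testing RMSE, then input order."""
    if not results:
        raise ValueError("no results to select from")
    return min(
        enumerate(results),
        key=lambda ir: (ir[1].test_accuracy.mape, ir[1].test_accuracy.rmse, ir[0]),
    )[1]


def default_specs(seed: int = DEFAULT_SEED, restarts: int = 50) -> list[RegressorSpec]:
    """The ten reference second-stage configurations: two KNN weightings,
    four SVR kernels, the RF, GBM and ANN setups."""
    specs = [
        RegressorSpec("knn", {"weights": "uniform"}, seed=seed),
        RegressorSpec("knn", {"weights": "inverse"}, seed=seed),
    ]
    specs += [RegressorSpec("svr", {"kernel": k}, seed=seed) for k in _SVR_KERNELS]
    specs += [
        RegressorSpec("rf", seed=seed),
        RegressorSpec("gbm", seed=seed),
        RegressorSpec("ann", seed=seed, restarts=restarts),
    ]
    return specs


def results_table(results: list[HybridResult], decimals: int | None = 2) -> pd.DataFrame:
    """Accuracy-table export: one training and one testing row per result."""
    rows = []
    for res in results:
        for group, rep in (("training", res.train_accuracy), ("testing", res.test_accuracy)):
            rows.append(
                {
                    "model": res.spec.label,
                    "family": res.spec.family,
                    "group": group,
                    **rep.as_row(decimals),
                }
            )
    return pd.DataFrame(rows)
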