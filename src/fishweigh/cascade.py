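"""The three-stage weight-estimation cascade (depth -> cm -> weight).

Monocular weight estimation cannot read distance directly, so the pipeline
chains three regressions, each feeding the next:

1. depth: (age, length_px, width_px) -> camera-to-fish depth in cm,
2. pixel-to-centimetre: the same features plus depth -> (length_cm,
   width_cm), one single-target regressor per output,
3. weight: all of the above -> weight in grams.

Stages are trained on annotated values (measured pixel dimensions,
marker-read depth labels, tape-measured centimetre dimensions) and chained
at prediction time on their own upstream estimates.  Three regression
families are supported per stage — ordinary least squares (LR), random
forest regression (RFR, shallow trees), and epsilon-insensitive RBF
support vector regression (SVR, on standardised features) — with the
default assignment SVR / LR / LR, selectable per stage or via grid search
on a held-out validation split.

:class:`CascadeWeightEstimator` is a scikit-learn style estimator
(``fit`` / ``predict`` / ``get_params``); the module-level functions
(`split_dataset`, `fit_regressor`, `grid_search`, `train_cascade`,
`predict_cascade`, `evaluate_cascade`) are thin wrappers over it and the
underlying scikit-learn regressors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted

from .metrics import MetricsReport, mae

__all__ = [
    "SplitSpec",
    "RegressorSpec",
    "split_dataset",
    "make_regressor",
    "fit_regressor",
    "grid_search",
    "CascadeWeightEstimator",
    "train_cascade",
    "predict_cascade",
    "evaluate_cascade",
    "nine_case_reports",
    "save_cascade",
    "load_cascade",
    "DEFAULT_SVR_GRID",
    "DEFAULT_RFR_GRID",
    "NINE_CASE_LABELS",
]

FAMILIES = ("LR", "RFR", "SVR")

#: Table-1 style feature wiring of the three stages.
DEPTH_FEATURES = ["age_weeks", "length_px", "width_px"]
DEPTH_TARGET = "depth_label_cm"
SIZE_FEATURES = DEPTH_FEATURES + [DEPTH_TARGET]
SIZE_TARGETS = ["length_cm", "width_cm"]
WEIGHT_FEATURES = SIZE_FEATURES + SIZE_TARGETS
WEIGHT_TARGET = "weight_g"

DEFAULT_SVR_GRID = {
    "C": [0.1, 1.0, 10.0, 100.0],
    "gamma": [0.001, 0.01, 0.1, 1.0],
    "epsilon": [0.01, 0.1, 1.0],
}
DEFAULT_RFR_GRID = {
    "max_depth": [2],
    "n_estimators": [50, 100, 200],
    "min_samples_leaf": [1, 5],
}

NINE_CASE_LABELS = ("SSL", "SSR", "SSS", "SRL", "SRR", "SRS",
                    "SLL", "SLR", "SLS")
_LETTER_TO_FAMILY = {"S": "SVR", "R": "RFR", "L": "LR"}


@dataclass(frozen=True)
class SplitSpec:
    """Two-level split: test carved off first, then train/validation."""

    outer_train_frac: float = 0.7
    inner_train_frac: float = 0.8
    seed: int = 0

    def __post_init__(self):
        for f in (self.outer_train_frac, self.inner_train_frac):
            if not 0.0 < f <= 1.0:
                raise ValueError("split fractions must lie in (0, 1]")


@dataclass(frozen=True)
class RegressorSpec:
    """A regression family plus its hyperparameters."""

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")


def split_dataset(n: int, spec: SplitSpec | None = None):
    """Seed-shuffled (train, validation, test) index arrays.

    Sizes follow nearest rounding with ties to even at each level:
    the train+validation pool is round(n * outer_train_frac) rows, of
    which round(pool * inner_train_frac) are training rows.  Partitions
    are disjoint and exhaustive.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    spec = spec or SplitSpec()
    n_pool = round(n * spec.outer_train_frac)
    n_train = round(n_pool * spec.inner_train_frac)
    n_val = n_pool - n_train
    n_test = n - n_pool
    if min(n_train, n_val, n_test) == 0:
        warnings.warn(
            f"empty partition in split of n={n}: sizes "
            f"({n_train}, {n_val}, {n_test})", UserWarning, stacklevel=2)
    perm = np.random.default_rng(spec.seed).permutation(n)
    return perm[:n_train], perm[n_train:n_pool], perm[n_pool:]


def make_regressor(spec: RegressorSpec, seed: int = 0):
    """Instantiate the scikit-learn regressor behind a spec.

    SVR is wrapped in a feature-standardisation pipeline (mean 0, SD 1 on
    the training set); LR and RFR fit raw features.
    """
    if spec.family == "LR":
        return LinearRegression(**spec.params)
    if spec.family == "RFR":
        params = {"max_depth": 2, "n_estimators": 100, **spec.params}
        return RandomForestRegressor(random_state=seed, **params)
    params = {"kernel": "rbf", "C": 100.0, "gamma": "scale", "epsilon": 0.1,
              **spec.params}
    return Pipeline([("scale", StandardScaler()), ("svr", SVR(**params))])


def fit_regressor(spec: RegressorSpec, features, targets, seed: int = 0):
    """Fit one regressor on a feature matrix and target vector."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("features must be a 2-D matrix with >= 1 column")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and targets disagree in length")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    if spec.family == "LR":
        design = np.hstack([np.ones((X.shape[0], 1)), X])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            warnings.warn("rank-deficient design: minimum-norm LR solution",
                          UserWarning, stacklevel=2)
    model = make_regressor(spec, seed=seed)
    return model.fit(X, y)


def grid_search(family: str, grid: dict, train, val, seed: int = 0) -> RegressorSpec:
    """Exhaustive hyperparameter search minimising validation MAE.

    ``train`` and ``val`` are (X, y) pairs on disjoint rows.  Every
    Cartesian combination of the grid is fitted; ties keep the first
    combination in deterministic iteration order.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X_tr, y_tr = train
    X_val, y_val = val
    keys = list(grid)
    best_spec, best_mae = None, np.inf
    for combo in itertools.product(*(grid[k] for k in keys)):
        spec = RegressorSpec(family, dict(zip(keys, combo)))
        model = fit_regressor(spec, X_tr, y_tr, seed=seed)
        score = mae(y_val, model.predict(np.asarray(X_val, dtype=float)))
        if score < best_mae:
            best_spec, best_mae = spec, score
    return best_spec


def _require_columns(data: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in data.columns]
    if missing:
        raise KeyError(f"dataset is missing required column(s): {missing}")


class CascadeWeightEstimator(BaseEstimator, RegressorMixin):
    """Chained depth / pixel-to-cm / weight regression cascade.

    Parameters
    ----------
    depth_spec, size_spec, weight_spec : RegressorSpec, optional
        Per-stage family and hyperparameters.  Defaults: SVR for depth,
        LR for the centimetre conversion, LR for weight.
    depth_grid, size_grid, weight_grid : dict, optional
        When given, a validation-split grid search over these values
        selects the stage's hyperparameters instead of the fixed spec.
    split : SplitSpec, optional
        Train / validation / test partition of the input table.
    seed : int
        Seeds the split shuffle and any stochastic regressor.

    Attributes
    ----------
    depth_model_, length_model_, width_model_, weight_model_ : fitted regressors
    depth_spec_, size_spec_, weight_spec_ : the specs actually used
    residual_summaries_ : dict
        Validation-split signed-residual (mean, SD) per stage.
    split_indices_ : (train, val, test) row-index arrays of the fit table.
    """

    def __init__(self, depth_spec=None, size_spec=None, weight_spec=None,
                 depth_grid=None, size_grid=None, weight_grid=None,
                 split=None, seed: int = 0):
        self.depth_spec = depth_spec
        self.size_spec = size_spec
        self.weight_spec = weight_spec
        self.depth_grid = depth_grid
        self.size_grid = size_grid
        self.weight_grid = weight_grid
        self.split = split
        self.seed = seed

    # -- fitting ---------------------------------------------------------

    def _resolve_stage(self, spec, grid, family_default, X_tr, y_tr, X_val, y_val):
        if grid is not None:
            family = spec.family if spec is not None else family_default
            chosen = grid_search(family, grid, (X_tr, y_tr), (X_val, y_val),
                                 seed=self.seed)
        else:
            chosen = spec if spec is not None else RegressorSpec(family_default)
        model = fit_regressor(chosen, X_tr, y_tr, seed=self.seed)
        return chosen, model

    def fit(self, X: pd.DataFrame, y=None):
        """Fit all stages on the annotation columns of the observation table.

        ``y`` defaults to the table's ``weight_g`` column; passing it
        explicitly overrides the weight-stage target.
        """
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame of observations")
        _require_columns(X, WEIGHT_FEATURES)
        if y is None:
            _require_columns(X, [WEIGHT_TARGET])
            y = X[WEIGHT_TARGET]
        y = np.asarray(y, dtype=float)
        n = len(X)
        if n < 10:
            warnings.warn(f"only {n} rows: cascade fit is under-determined",
                          UserWarning, stacklevel=2)
        split = self.split or SplitSpec(seed=self.seed)
        tr, va, te = split_dataset(n, split)
        if len(va) == 0:  # fall back: validate on the training rows
            va = tr

        def stage_xy(features, target):
            Xm = X[features].to_numpy(dtype=float)
            t = y if target is WEIGHT_TARGET else X[target].to_numpy(dtype=float)
            return Xm[tr], t[tr], Xm[va], t[va]

        self.residual_summaries_ = {}

        X_tr, y_tr, X_val, y_val = stage_xy(DEPTH_FEATURES, DEPTH_TARGET)
        self.depth_spec_, self.depth_model_ = self._resolve_stage(
            self.depth_spec, self.depth_grid, "SVR", X_tr, y_tr, X_val, y_val)
        res = self.depth_model_.predict(X_val) - y_val
        self.residual_summaries_["depth"] = (float(res.mean()), float(res.std(ddof=1)))

        self.size_spec_ = None
        for target in SIZE_TARGETS:
            X_tr, y_tr, X_val, y_val = stage_xy(SIZE_FEATURES, target)
            spec, model = self._resolve_stage(
                self.size_spec, self.size_grid, "LR", X_tr, y_tr, X_val, y_val)
            if target == "length_cm":
                self.length_model_ = model
            else:
                self.width_model_ = model
            self.size_spec_ = self.size_spec_ or spec
            res = model.predict(X_val) - y_val
            self.residual_summaries_[target] = (float(res.mean()), float(res.std(ddof=1)))

        X_tr, y_tr, X_val, y_val = stage_xy(WEIGHT_FEATURES, WEIGHT_TARGET)
        self.weight_spec_, self.weight_model_ = self._resolve_stage(
            self.weight_spec, self.weight_grid, "LR", X_tr, y_tr, X_val, y_val)
        res = self.weight_model_.predict(X_val) - y_val
        self.residual_summaries_["weight"] = (float(res.mean()), float(res.std(ddof=1)))

        self.split_indices_ = (tr, va, te)
        self.n_features_in_ = len(DEPTH_FEATURES)
        return self

    # -- prediction ------------------------------------------------------

    @staticmethod
    def _predict_features(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            _require_columns(X, DEPTH_FEATURES)
            return X[DEPTH_FEATURES].to_numpy(dtype=float)
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(
                "expected columns (age_weeks, length_px, width_px)")
        return arr

    def predict_stages(self, X) -> pd.DataFrame:
        """All four chained estimates per fish: depth, length, width, weight.

        Each stage consumes the previous stage's *predictions*, exactly as
        deployed: estimated depth enters the centimetre conversion, and
        estimated centimetre dimensions enter the weight stage.
        """
        check_is_fitted(self, "weight_model_")
        A = self._predict_features(X)
        if A.shape[0] == 0:
            return pd.DataFrame(columns=["depth_cm", "length_cm", "width_cm",
                                         "weight_g"])
        depth = self.depth_model_.predict(A)
        size_in = np.column_stack([A, depth])
        length_cm = self.length_model_.predict(size_in)
        width_cm = self.width_model_.predict(size_in)
        weight_in = np.column_stack([size_in, length_cm, width_cm])
        weight = self.weight_model_.predict(weight_in)
        return pd.DataFrame({
            "depth_cm": depth, "length_cm": length_cm,
            "width_cm": width_cm, "weight_g": weight,
        })

    def predict(self, X) -> np.ndarray:
        """Predicted weight in grams."""
        return self.predict_stages(X)["weight_g"].to_numpy()


def train_cascade(data: pd.DataFrame, config: dict | None = None,
                  split: SplitSpec | None = None,
                  seed: int = 0) -> CascadeWeightEstimator:
    """Fit a cascade on an observation table.

    ``config`` may carry per-stage ``*_spec`` RegressorSpec entries and/or
    ``*_grid`` hyperparameter grids (keys ``depth``, ``size``, ``weight``).
    """
    config = config or {}
    est = CascadeWeightEstimator(
        depth_spec=config.get("depth_spec"),
        size_spec=config.get("size_spec"),
        weight_spec=config.get("weight_spec"),
        depth_grid=config.get("depth_grid"),
        size_grid=config.get("size_grid"),
        weight_grid=config.get("weight_grid"),
        split=split, seed=seed)
    return est.fit(data)


def predict_cascade(observations, model: CascadeWeightEstimator) -> pd.DataFrame:
    """Chained per-fish estimates for a stream of (age, length_px, width_px)."""
    if isinstance(observations, pd.DataFrame):
        return model.predict_stages(observations)
    rows = list(observations)
    arr = np.asarray(rows, dtype=float).reshape(len(rows), -1) if rows else \
        np.empty((0, 3))
    return model.predict_stages(arr)


def evaluate_cascade(model: CascadeWeightEstimator, data: pd.DataFrame,
                     indices=None) -> dict[str, MetricsReport]:
    """Per-stage test-split metrics of a fitted cascade.

    Predictions are chained (deployment conditions); actuals are the
    annotation columns.  ``indices`` defaults to the fit-time test split.
    """
    check_is_fitted(model, "split_indices_")
    if indices is None:
        indices = model.split_indices_[2]
    test = data.iloc[np.asarray(indices)]
    stages = model.predict_stages(test)
    return {
        "depth": MetricsReport.from_predictions(
            test[DEPTH_TARGET], stages["depth_cm"]),
        "length_cm": MetricsReport.from_predictions(
            test["length_cm"], stages["length_cm"]),
        "width_cm": MetricsReport.from_predictions(
            test["width_cm"], stages["width_cm"]),
        "weight": MetricsReport.from_predictions(
            test[WEIGHT_TARGET], stages["weight_g"]),
    }


def nine_case_reports(data: pd.DataFrame, split: SplitSpec | None = None,
                      seed: int = 0) -> dict[str, MetricsReport]:
    """Weight metrics of the nine family assignments SSL ... SLS.

    The first letter is the (fixed, SVR) depth stage; the second and third
    letters assign SVR/RFR/LR to the centimetre-conversion and weight
    stages respectively.
    """
    reports = {}
    for label in NINE_CASE_LABELS:
        est = CascadeWeightEstimator(
            depth_spec=RegressorSpec(_LETTER_TO_FAMILY[label[0]]),
            size_spec=RegressorSpec(_LETTER_TO_FAMILY[label[1]]),
            weight_spec=RegressorSpec(_LETTER_TO_FAMILY[label[2]]),
            split=split, seed=seed).fit(data)
        reports[label] = evaluate_cascade(est, data)["weight"]
    return reports


_PERSIST_VERSION = 1


def save_cascade(model: CascadeWeightEstimator, path) -> None:
    """Persist a fitted cascade (versioned archive; round-trips exactly)."""
    check_is_fitted(model, "weight_model_")
    joblib.dump({"format_version": _PERSIST_VERSION, "estimator": model}, path)


def load_cascade(path) -> CascadeWeightEstimator:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != _PERSIST_VERSION:
        raise ValueError(f"unsupported cascade archive version: {version}")
    return payload["estimator"]
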