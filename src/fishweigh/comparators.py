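"""Area-based weight estimators used as head-to-head baselines.

A family of seven closed forms maps a fish's body area A (length x width
x a coefficient, in cm²) directly to weight in grams: two power laws, an
exponential, a linear, a logarithmic, and a quadratic curve, plus a power
law with a fixed 3/2 exponent.  The default coefficients are the published
calibration constants of each form; each family can also be refitted to
(A, W) pairs by ordinary least squares in its natural space — raw space
for linear / logarithmic / quadratic, log space for the exponential and
power families (deterministic and exact on noiseless data, documented
because log-space and raw-space fits differ on noisy data).

:class:`AreaWeightRegressor` exposes the fit/predict estimator surface;
`fish_area`, `area_weight`, `fit_comparator` and `compare_methods` are the
functional interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .metrics import MetricsReport

__all__ = [
    "ComparatorSpec",
    "DEFAULT_COMPARATORS",
    "fish_area",
    "area_weight",
    "fit_comparator",
    "compare_methods",
    "AreaWeightRegressor",
]

#: form name -> number of coefficients
_ARITY = {
    "power_fixed": 2,   # a * A^b with b frozen (only a is fitted)
    "power": 2,         # a * A^b
    "exponential": 2,   # a * exp(b * A)
    "linear": 2,        # a * A + b
    "logarithmic": 2,   # a * ln(A) + b
    "polynomial2": 3,   # a * A^2 + b * A + c
}


@dataclass(frozen=True)
class ComparatorSpec:
    """One area-to-weight closed form with its coefficients."""

    form: str
    coefficients: tuple
    area_coefficient: float = 1.0

    def __post_init__(self):
        if self.form not in _ARITY:
            raise ValueError(f"unknown form {self.form!r}")
        if len(self.coefficients) != _ARITY[self.form]:
            raise ValueError(
                f"{self.form} expects {_ARITY[self.form]} coefficients, "
                f"got {len(self.coefficients)}")
        if not self.area_coefficient > 0:
            raise ValueError("area_coefficient must be positive")


#: The seven published calibrations, W1..W7.
DEFAULT_COMPARATORS = {
    "W1": ComparatorSpec("power_fixed", (1.70, 1.5)),
    "W2": ComparatorSpec("power", (0.124, 1.55)),
    "W3": ComparatorSpec("exponential", (75.505, 0.008)),
    "W4": ComparatorSpec("linear", (2.6609, -141.14)),
    "W5": ComparatorSpec("logarithmic", (448.84, -1984.1)),
    "W6": ComparatorSpec("polynomial2", (0.0048, 0.9309, 7.8245)),
    "W7": ComparatorSpec("power", (0.2501, 1.3821)),
}


def fish_area(length_cm, width_cm, area_coefficient: float = 1.0):
    """Body area A = length x width x coefficient, in cm²."""
    length = np.asarray(length_cm, dtype=float)
    width = np.asarray(width_cm, dtype=float)
    if np.any(length <= 0) or np.any(width <= 0):
        raise ValueError("length and width must be positive")
    if not area_coefficient > 0:
        raise ValueError("area_coefficient must be positive")
    out = length * width * area_coefficient
    return float(out) if out.ndim == 0 else out


def area_weight(spec: ComparatorSpec, area):
    """Evaluate the closed form at area(s) A, returning grams."""
    A = np.asarray(area, dtype=float)
    if np.any(A < 0):
        raise ValueError("area must be non-negative")
    c = spec.coefficients
    if spec.form in ("power_fixed", "power"):
        out = c[0] * A ** c[1]
    elif spec.form == "exponential":
        out = c[0] * np.exp(c[1] * A)
    elif spec.form == "linear":
        out = c[0] * A + c[1]
    elif spec.form == "logarithmic":
        if np.any(A <= 0):
            raise ValueError("logarithmic form requires A > 0")
        out = c[0] * np.log(A) + c[1]
    else:  # polynomial2
        out = c[0] * A**2 + c[1] * A + c[2]
    return float(out) if out.ndim == 0 else out


def _check_fit_inputs(form: str, A: np.ndarray, W: np.ndarray):
    if A.shape != W.shape or A.ndim != 1:
        raise ValueError("A and W must be aligned 1-D vectors")
    if np.unique(A).size < _ARITY[form]:
        raise ValueError(
            f"degenerate design: {form} needs at least {_ARITY[form]} "
            "distinct areas")
    if np.any(A <= 0) and form in ("power_fixed", "power", "logarithmic"):
        raise ValueError(f"{form} fit requires positive areas; offending rows: "
                         f"{np.flatnonzero(A <= 0).tolist()}")
    if np.any(W <= 0) and form in ("power_fixed", "power", "exponential"):
        raise ValueError(
            f"{form} fit requires positive weights (log transform); offending "
            f"rows: {np.flatnonzero(W <= 0).tolist()}")


def fit_comparator(form: str, areas, weights) -> tuple[ComparatorSpec, float]:
    """Least-squares calibration of one family to (A, W) pairs.

    Returns the fitted spec and the residual sum of squares *in the space
    where the OLS was solved*: raw grams for linear / logarithmic /
    polynomial2, log-grams for power / power_fixed / exponential.
    """
    if form not in _ARITY:
        raise ValueError(f"unknown form {form!r}")
    A = np.asarray(areas, dtype=float).ravel()
    W = np.asarray(weights, dtype=float).ravel()
    _check_fit_inputs(form, A, W)

    def ols(X, y):
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ coef) ** 2))
        return coef, rss

    if form == "linear":
        coef, rss = ols(np.column_stack([A, np.ones_like(A)]), W)
        spec = ComparatorSpec(form, (float(coef[0]), float(coef[1])))
    elif form == "logarithmic":
        coef, rss = ols(np.column_stack([np.log(A), np.ones_like(A)]), W)
        spec = ComparatorSpec(form, (float(coef[0]), float(coef[1])))
    elif form == "polynomial2":
        coef, rss = ols(np.column_stack([A**2, A, np.ones_like(A)]), W)
        spec = ComparatorSpec(form, tuple(float(x) for x in coef))
    elif form == "exponential":
        coef, rss = ols(np.column_stack([A, np.ones_like(A)]), np.log(W))
        spec = ComparatorSpec(form, (float(np.exp(coef[1])), float(coef[0])))
    elif form == "power":
        coef, rss = ols(np.column_stack([np.log(A), np.ones_like(A)]), np.log(W))
        spec = ComparatorSpec(form, (float(np.exp(coef[1])), float(coef[0])))
    else:  # power_fixed: exponent frozen at 1.5, scale fitted in log space
        b = 1.5
        resid = np.log(W) - b * np.log(A)
        log_a = float(resid.mean())
        rss = float(np.sum((resid - log_a) ** 2))
        spec = ComparatorSpec(form, (float(np.exp(log_a)), b))
    return spec, rss


def compare_methods(specs, areas, cascade_predictions, actual_weights,
                    cascade_label: str = "cascade") -> pd.DataFrame:
    """Head-to-head metrics table: one row per area form plus the cascade.

    ``specs`` maps method name -> ComparatorSpec (defaults to W1..W7).
    All inputs must be aligned on the same fish.
    """
    specs = DEFAULT_COMPARATORS if specs is None else specs
    A = np.asarray(areas, dtype=float).ravel()
    yhat_cascade = np.asarray(cascade_predictions, dtype=float).ravel()
    y = np.asarray(actual_weights, dtype=float).ravel()
    if not (A.shape == yhat_cascade.shape == y.shape):
        raise ValueError("areas, cascade predictions, and actual weights must "
                         "be aligned on the same fish")
    rows = {}
    for name, spec in specs.items():
        rows[name] = MetricsReport.from_predictions(y, area_weight(spec, A)).as_dict()
    rows[cascade_label] = MetricsReport.from_predictions(y, yhat_cascade).as_dict()
    return pd.DataFrame.from_dict(rows, orient="index")


class AreaWeightRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn estimator wrapper around one area-to-weight family.

    ``X`` may be a single column of areas (cm²) or two columns
    (length_cm, width_cm) which are converted through ``fish_area``;
    ``y`` is the weight in grams.  Without calling ``fit`` the published
    default coefficients of the chosen form are not used — call
    ``from_spec`` for a pre-calibrated predictor.
    """

    def __init__(self, form: str = "power", area_coefficient: float = 1.0):
        self.form = form
        self.area_coefficient = area_coefficient

    @classmethod
    def from_spec(cls, spec: ComparatorSpec) -> "AreaWeightRegressor":
        est = cls(form=spec.form, area_coefficient=spec.area_coefficient)
        est.spec_ = spec
        est.rss_ = np.nan
        return est

    def _areas(self, X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[1] == 1:
            return arr[:, 0]
        if arr.shape[1] == 2:
            return fish_area(arr[:, 0], arr[:, 1], self.area_coefficient)
        raise ValueError("X must have 1 (area) or 2 (length, width) columns")

    def fit(self, X, y):
        A = self._areas(X)
        self.spec_, self.rss_ = fit_comparator(self.form, A, y)
        arr = np.asarray(X, dtype=float)
        self.n_features_in_ = 1 if arr.ndim == 1 else arr.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "spec_")
        return np.asarray(area_weight(self.spec_, self._areas(X)), dtype=float)
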