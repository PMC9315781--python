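"""Evaluation statistics shared across the pipeline.

Every stage of the weight-estimation cascade — depth, pixel-to-centimetre
conversion, and weight — is scored with the same small set of statistics:
mean absolute error (MAE), the coefficient of determination R², the MAE
ratio (MAE divided by R², a single figure that penalises both large errors
and poor fit; negative whenever R² is negative out-of-sample), and the
mean and sample standard deviation of the signed errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "mae",
    "r2",
    "mae_ratio",
    "error_stats",
    "MetricsReport",
]


def _pair(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(actual, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(
            f"length mismatch: {y.shape[0]} actual vs {yhat.shape[0]} predicted"
        )
    if y.size == 0:
        raise ValueError("empty input")
    return y, yhat


def mae(actual, predicted) -> float:
    """Mean absolute error, mean(|y_i - yhat_i|)."""
    y, yhat = _pair(actual, predicted)
    return float(np.mean(np.abs(y - yhat)))


def r2(actual, predicted) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    Can be negative when the predictions are worse than the constant mean
    predictor (routine for out-of-sample scores).
    """
    y, yhat = _pair(actual, predicted)
    if y.size < 2:
        raise ValueError("r2 requires at least 2 samples")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r2 undefined: actual values have zero variance")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def mae_ratio(mae_value: float, r2_value: float) -> float:
    """MAE divided by R².

    A compact ranking figure: small when the error is low *and* the fit is
    good.  Negative whenever R² is negative, so poorly generalising models
    sort below everything else by |ratio| blow-up.
    """
    if r2_value == 0.0:
        raise ZeroDivisionError("MAE ratio undefined for r2 = 0")
    return mae_value / r2_value


def error_stats(actual, predicted) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of signed errors (predicted - actual)."""
    y, yhat = _pair(actual, predicted)
    if y.size < 2:
        raise ValueError("error SD undefined for fewer than 2 samples")
    err = yhat - y
    return float(err.mean()), float(err.std(ddof=1))


@dataclass(frozen=True)
class MetricsReport:
    """One prediction set's scores: MAE, R², MAE ratio, signed-error mean/SD."""

    mae: float
    r2: float
    mae_ratio: float
    mean_error: float
    sd_error: float
    n: int

    @classmethod
    def from_predictions(cls, actual, predicted) -> "MetricsReport":
        y, yhat = _pair(actual, predicted)
        m = mae(y, yhat)
        r = r2(y, yhat)
        ratio = mae_ratio(m, r) if r != 0.0 else math.nan
        mean_err, sd_err = error_stats(y, yhat)
        return cls(mae=m, r2=r, mae_ratio=ratio,
                   mean_error=mean_err, sd_error=sd_err, n=int(y.size))

    def as_dict(self) -> dict:
        return asdict(self)
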