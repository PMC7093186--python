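"""Prediction-quality metrics and tissue ageing-rate estimation.

Error naming follows the clock literature's reporting convention: RMSE is the
root mean squared error, MAD the *mean* absolute deviation and MAE the
*median* absolute error of predicted minus actual age, all in weeks.  The
ageing rate of a tissue relative to the training tissue is the OLS slope of
predicted on actual age: a slope below 1 (with a 95% CI excluding 1) means
methylation at the clock sites drifts more slowly than in the tissue the
clock was trained on.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = ["MetricSet", "RateEstimate", "evaluate", "estimate_tissue_rate"]


@dataclass(frozen=True)
class MetricSet:
    pearson_r: float
    rmse_weeks: float
    mad_weeks: float  # mean absolute deviation
    mae_weeks: float  # median absolute error
    n: int
    fitted_slope: float
    fitted_intercept: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RateEstimate:
    slope: float
    stderr: float
    ci_low: float
    ci_high: float
    n: int

    @property
    def differs_from_training_rate(self) -> bool:
        """True when the 95% CI excludes 1 (ageing rate differs)."""
        return not (self.ci_low <= 1.0 <= self.ci_high)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["differs_from_training_rate"] = self.differs_from_training_rate
        return d


def evaluate(predicted: np.ndarray, actual: np.ndarray) -> MetricSet:
    """Summarize predicted vs actual ages (weeks)."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have equal length")
    n = predicted.size
    if n < 2:
        raise ValueError("need n >= 2")
    resid = predicted - actual
    nan = float("nan")
    if np.ptp(predicted) == 0 or np.ptp(actual) == 0:
        r, slope, intercept = nan, nan, nan
        if np.ptp(actual) != 0:  # flat predictions still admit the OLS fit
            slope, intercept = 0.0, float(predicted[0])
    else:
        fit = stats.linregress(actual, predicted)
        r = float(stats.pearsonr(predicted, actual).statistic)
        slope, intercept = float(fit.slope), float(fit.intercept)
    return MetricSet(
        pearson_r=r,
        rmse_weeks=float(np.sqrt(np.mean(resid**2))),
        mad_weeks=float(np.mean(np.abs(resid))),
        mae_weeks=float(np.median(np.abs(resid))),
        n=n,
        fitted_slope=slope,
        fitted_intercept=intercept,
    )


def estimate_tissue_rate(predicted: np.ndarray, actual: np.ndarray) -> RateEstimate:
    """OLS slope of predicted on actual age with a t-based 95% CI."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    n = predicted.size
    if n < 3:
        raise ValueError("need n >= 3 for a slope CI")
    fit = stats.linregress(actual, predicted)
    if fit.stderr == 0:
        lo = hi = float(fit.slope)
    else:
        tcrit = stats.t.ppf(0.975, n - 2)
        lo = float(fit.slope - tcrit * fit.stderr)
        hi = float(fit.slope + tcrit * fit.stderr)
    return RateEstimate(float(fit.slope), float(fit.stderr), lo, hi, n)
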