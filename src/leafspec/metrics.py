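"""Regression-quality metrics for calibration, cross-validation and prediction.

Conventions match chemometric calibration reporting:

* R-squared is the squared Pearson correlation between measured and
  predicted values (the 1 - SS_res/SS_tot variant is also recorded).
* slope/offset come from ordinary least squares of predicted on measured,
  matching the axes of a predicted-vs-measured scatterplot.
* RPD = 1 / sqrt(1 - R^2), with the usual interpretation bands
  (>= 3 quality, 2-3 good, 1.5-2 medium, < 1.5 poor).
* SEP is the bias-corrected standard deviation of the residuals, so that
  rmse^2 = bias^2 + (n-1)/n * sep^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PHASES = ("calibration", "cross_validation", "prediction")


@dataclass
class FitReport:
    """Metric set for one model phase."""

    phase: str
    n: int
    r: float
    r2: float
    r2_ss: float  # 1 - SS_res/SS_tot, logged alongside the Pearson form
    slope: float
    offset: float
    rmse: float
    rpd: float
    bias: float
    sep: float
    residuals: np.ndarray = field(repr=False, default=None)


def regression_metrics(observed, predicted, phase: str) -> FitReport:
    """Compute the full metric set for one (measured, predicted) pairing."""
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}")
    y = np.asarray(observed, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("observed and predicted must have equal length")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.allclose(y, y[0]):
        raise ValueError("observed values have zero variance")

    r = float(np.corrcoef(y, yhat)[0, 1])
    r2 = r * r
    resid = yhat - y
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2_ss = 1.0 - float(np.sum(resid**2)) / ss_tot
    slope, offset = np.polyfit(y, yhat, 1)
    rmse = float(np.sqrt(np.mean(resid**2)))
    bias = float(resid.mean())
    sep = float(np.sqrt(np.sum((resid - bias) ** 2) / (n - 1)))
    rpd = rpd_from_r2(r2) if r2 < 1.0 else float("inf")
    return FitReport(
        phase=phase, n=n, r=r, r2=r2, r2_ss=r2_ss,
        slope=float(slope), offset=float(offset),
        rmse=rmse, rpd=rpd, bias=bias, sep=sep, residuals=resid,
    )


def rpd_from_r2(r2: float) -> float:
    """Ratio of performance to deviation, RPD = 1/sqrt(1 - R^2)."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError("r2 must lie in [0, 1)")
    return 1.0 / np.sqrt(1.0 - r2)


def classify_r2(r2: float) -> str:
    """Prediction-capacity band: excellent (> 0.75), good ([0.5, 0.75]), low."""
    if r2 > 0.75:
        return "excellent"
    if r2 >= 0.5:
        return "good"
    return "low"


def classify_rpd(rpd: float) -> str:
    """Analytical-performance band: quality (>= 3), good, medium, poor."""
    if rpd >= 3.0:
        return "quality"
    if rpd >= 2.0:
        return "good"
    if rpd >= 1.5:
        return "medium"
    return "poor"


def band_correlation(absorbance_at_band, reflectance_at_band) -> float:
    """Pearson correlation across leaves between A and R at one wavelength.

    Used at the 435/550/674 nm blue/green/red probe bands to quantify how
    far the two channels are from perfect complementarity.
    """
    a = np.asarray(absorbance_at_band, dtype=float).ravel()
    r = np.asarray(reflectance_at_band, dtype=float).ravel()
    if a.size != r.size:
        raise ValueError("paired samples required")
    if a.size < 3:
        raise ValueError("need at least 3 paired samples")
    return float(np.corrcoef(a, r)[0, 1])
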