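"""Forecast accuracy statistics: RMSE, FIT and NPE.

For measured glucose G_i and predictions Ghat_i (both mmol/L, i = 1..N):

* ``RMSE  = sqrt( sum (G_i - Ghat_i)^2 / N )``          (mmol/L)
* ``FIT   = (1 - ||G - Ghat|| / ||G - Gbar||) * 100``   (%)
* ``NPE   = sqrt( sum (G_i - Ghat_i)^2 / sum G_i^2 ) * 100``  (%)

with Euclidean norms and Gbar the mean of the measured series. FIT is 100%
for a perfect forecast, exactly 0% for the constant-mean predictor, and
negative for anything worse than the mean; it is not clipped.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


@dataclasses.dataclass(frozen=True)
class PredictionResult:
    """Aligned (measured, predicted) glucose pairs at one stated horizon."""

    measured: np.ndarray
    predicted: np.ndarray
    horizon_minutes: float

    def __post_init__(self) -> None:
        m = np.asarray(self.measured, dtype=float)
        p = np.asarray(self.predicted, dtype=float)
        object.__setattr__(self, "measured", m)
        object.__setattr__(self, "predicted", p)
        if m.shape != p.shape:
            raise ValueError(f"length mismatch: {m.shape} vs {p.shape}")
        if m.ndim != 1 or len(m) < 2:
            raise ValueError("need at least 2 aligned pairs")
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(p))):
            raise ValueError("non-finite values in prediction result")


def rmse(r: PredictionResult) -> float:
    """Root-mean-squared prediction error in mmol/L."""
    return float(np.sqrt(np.mean((r.measured - r.predicted) ** 2)))


def fit_percent(r: PredictionResult) -> float:
    """Percentage of the measured variation explained by the forecast."""
    denom = float(np.linalg.norm(r.measured - np.mean(r.measured)))
    if denom == 0.0:
        raise ValueError("FIT undefined for a constant measured sequence")
    num = float(np.linalg.norm(r.measured - r.predicted))
    return (1.0 - num / denom) * 100.0


def npe_percent(r: PredictionResult) -> float:
    """Residual norm as a percentage of the measured signal norm."""
    denom = float(np.sum(r.measured**2))
    if denom == 0.0:
        raise ValueError("NPE undefined when all measured values are zero")
    return float(np.sqrt(np.sum((r.measured - r.predicted) ** 2) / denom)) * 100.0


def metric_table(results: list[PredictionResult]) -> pd.DataFrame:
    """One row per horizon with NPE, RMSE and FIT, sorted by horizon.

    Columns: ``ph_min, npe_percent, rmse_mmol_per_l, fit_percent``.
    """
    if not results:
        raise ValueError("need at least one prediction result")
    phs = [r.horizon_minutes for r in results]
    if len(set(phs)) != len(phs):
        raise ValueError("duplicate prediction horizons")
    rows = [
        {
            "ph_min": r.horizon_minutes,
            "npe_percent": npe_percent(r),
            "rmse_mmol_per_l": rmse(r),
            "fit_percent": fit_percent(r),
        }
        for r in results
    ]
    return pd.DataFrame(rows).sort_values("ph_min").reset_index(drop=True)
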