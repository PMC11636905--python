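"""Smoothing, training-window construction and input scaling.

CGM traces are smoothed with a centred moving average (span 11 by default)
before any training or evaluation; smoothing reduces sensor noise and the
lag between predicted and observed glucose. Training material is cut into
40-sample windows — 20 consecutive inputs followed by the next 20 targets —
and all network inputs/targets are affinely mapped to [-1, 1] so the tanh
hidden units operate in their active range.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .timeseries_io import GlucoseSeries

N_IN_DEFAULT = 20
N_OUT_DEFAULT = 20


@dataclasses.dataclass(frozen=True)
class TrainingWindow:
    """One 40-sample training unit: 20 inputs then the next 20 targets,
    contiguous in the source segment starting at ``origin_index``."""

    inputs: np.ndarray
    targets: np.ndarray
    origin_index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", np.asarray(self.inputs, dtype=float))
        object.__setattr__(self, "targets", np.asarray(self.targets, dtype=float))


@dataclasses.dataclass(frozen=True)
class Scaler:
    """Affine map from glucose range [lo, hi] (mmol/L) onto [-1, 1]."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.hi > self.lo:
            raise ValueError(f"scaler needs hi > lo, got lo={self.lo} hi={self.hi}")


def moving_average_smooth(values: np.ndarray, span: int = 11) -> np.ndarray:
    """Centred moving average with shrinking symmetric endpoint windows.

    Interior point ``i`` is the mean of the ``span`` values centred on it.
    Near the ends the window shrinks symmetrically to size
    ``2*min(i, n-1-i) + 1``, so the first and last points pass through
    unchanged. Output length equals input length.
    """
    if span % 2 == 0 or span < 1:
        raise ValueError(f"span must be odd and positive, got {span}")
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("values must be a non-empty 1-D sequence")
    n = len(x)
    half = (span - 1) // 2
    # cumulative sum with leading zero: window sum = cs[j+1] - cs[i]
    cs = np.concatenate(([0.0], np.cumsum(x)))
    out = np.empty(n)
    idx = np.arange(n)
    h = np.minimum(np.minimum(idx, n - 1 - idx), half)
    lo = idx - h
    hi = idx + h
    out = (cs[hi + 1] - cs[lo]) / (2 * h + 1)
    # size-1 endpoint windows are exact pass-throughs, not cumsum differences
    out[h == 0] = x[h == 0]
    return out


def smooth_series(series: GlucoseSeries, span: int = 11) -> GlucoseSeries:
    """Return a copy of the series with moving-average-smoothed values."""
    return GlucoseSeries(
        times=series.times,
        values=moving_average_smooth(series.values, span=span),
        sampling_period=series.sampling_period,
        subject_id=series.subject_id,
    )


def make_windows(
    segment: GlucoseSeries,
    n_in: int = N_IN_DEFAULT,
    n_out: int = N_OUT_DEFAULT,
    stride: int = 1,
) -> list[TrainingWindow]:
    """Cut sliding (n_in inputs, n_out targets) windows from a segment.

    Windows start at indices 0, stride, 2*stride, ...; the count is
    ``floor((L - n_in - n_out)/stride) + 1`` for segment length
    ``L >= n_in + n_out``, else the empty list.
    """
    if n_in < 1 or n_out < 1 or stride < 1:
        raise ValueError("n_in, n_out and stride must be >= 1")
    v = segment.values
    total = n_in + n_out
    if len(v) < total:
        return []
    windows = []
    for start in range(0, len(v) - total + 1, stride):
        windows.append(
            TrainingWindow(
                inputs=v[start : start + n_in],
                targets=v[start + n_in : start + total],
                origin_index=start,
            )
        )
    return windows


def fit_scaler(values: np.ndarray) -> Scaler:
    """Fit the [-1, 1] scaler to the min/max of the training values."""
    x = np.asarray(values, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise ValueError("cannot fit a scaler to constant values")
    return Scaler(lo=lo, hi=hi)


def apply_scaler(s: Scaler, values):
    """Map glucose onto [-1, 1]: ``x -> 2*(x - lo)/(hi - lo) - 1``.

    Out-of-range values map linearly outside [-1, 1]; no clipping.
    """
    return 2.0 * (np.asarray(values, dtype=float) - s.lo) / (s.hi - s.lo) - 1.0


def invert_scaler(s: Scaler, scaled):
    """Exact inverse of :func:`apply_scaler`."""
    return (np.asarray(scaled, dtype=float) + 1.0) * (s.hi - s.lo) / 2.0 + s.lo
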