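"""Reading, writing and segmenting uniformly sampled CGM glucose series.

The canonical in-memory object is :class:`GlucoseSeries`: glucose in mmol/L
sampled on a strict 5-minute grid (288 samples/day, the usual CGM cadence).
Raw sensor exports contain dropouts; :func:`segment_by_gaps` cuts the record
at every large gap so that downstream windowing never straddles missing data.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

#: mg/dl per mmol/L for glucose (molar-mass convention).
MGDL_PER_MMOL = 18.0182

#: Minimum segment length worth keeping: one 20-input/20-output window.
MIN_SEGMENT_SAMPLES = 40

CSV_HEADER = ("time_min", "glucose")


class CGMValidationError(ValueError):
    """A series violates the uniform-sampling / positivity contract."""


class CGMParseError(ValueError):
    """A CSV file could not be parsed as a glucose series."""


@dataclasses.dataclass(frozen=True)
class GlucoseSeries:
    """A uniformly sampled glucose signal.

    Parameters
    ----------
    times
        Minutes since series start, strictly increasing, spaced exactly
        ``sampling_period`` apart (tolerance 1e-9).
    values
        Glucose concentration in mmol/L; finite and strictly positive.
    sampling_period
        Sampling interval in minutes (5 for standard CGM).
    subject_id
        Opaque label carried through the pipeline.
    """

    times: np.ndarray
    values: np.ndarray
    sampling_period: float = 5.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise CGMValidationError("times and values must be 1-D arrays")
        if len(times) != len(values):
            raise CGMValidationError(
                f"length mismatch: {len(times)} times vs {len(values)} values"
            )
        if len(times) == 0:
            raise CGMValidationError("empty series is not a valid GlucoseSeries")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(values)):
            raise CGMValidationError("non-finite entries in series")
        if np.any(values <= 0):
            raise CGMValidationError("glucose values must be strictly positive")
        diffs = np.diff(times)
        if np.any(diffs <= 0):
            raise CGMValidationError("times must be strictly increasing")
        if np.any(np.abs(diffs - self.sampling_period) > 1e-9):
            raise CGMValidationError(
                "non-uniform sampling inside a segment "
                f"(expected period {self.sampling_period} min)"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    """Leading-samples split: the first ``n_test`` samples are held out for
    testing/validation and the remainder is used for training."""

    n_test: int = 500

    def __post_init__(self) -> None:
        if self.n_test <= 0:
            raise CGMValidationError("n_test must be positive")


def read_cgm_csv(path: str | Path, value_unit: str = "mmol/L") -> GlucoseSeries:
    """Read a two-column CGM CSV (``time_min,glucose``) into a GlucoseSeries.

    ``value_unit`` may be ``"mmol/L"`` (stored as-is) or ``"mg/dl"``
    (divided by 18.0182 on the way in); the in-memory unit is always mmol/L.
    """
    if value_unit not in ("mmol/L", "mg/dl"):
        raise ValueError(f"unsupported unit {value_unit!r}")
    path = Path(path)
    try:
        frame = pd.read_csv(path, header=0, names=list(CSV_HEADER))
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CGMParseError(f"{path}: {exc}") from exc
    if len(frame) == 0:
        raise CGMParseError(f"{path}: no data rows")
    for col in CSV_HEADER:
        bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()]
        if len(bad):
            # +2: one for the header row, one for 1-based line numbering
            raise CGMParseError(f"{path}: malformed {col!r} at line {bad[0] + 2}")
    times = frame["time_min"].to_numpy(dtype=float)
    values = frame["glucose"].to_numpy(dtype=float)
    if value_unit == "mg/dl":
        values = values / MGDL_PER_MMOL
    period = float(times[1] - times[0]) if len(times) > 1 else 5.0
    return GlucoseSeries(times=times, values=values, sampling_period=period,
                         subject_id=path.stem)


def write_cgm_csv(series: GlucoseSeries, path: str | Path) -> None:
    """Write a series as ``time_min,glucose`` CSV (mmol/L, full precision).

    Round-trips through :func:`read_cgm_csv` to better than 1e-9 mmol/L.
    """
    frame = pd.DataFrame({"time_min": series.times, "glucose": series.values})
    frame.to_csv(path, index=False, float_format="%.17g")


def segment_by_gaps(
    times: np.ndarray,
    values: np.ndarray,
    sampling_period: float = 5.0,
    max_gap: float | None = None,
    subject_id: str = "",
) -> list[GlucoseSeries]:
    """Split a raw (possibly gappy) record into uniformly sampled segments.

    The record is cut wherever consecutive timestamps differ by more than
    ``max_gap`` minutes (default twice the sampling period: one missed
    reading is tolerated, more is a gap). Segments shorter than
    ``MIN_SEGMENT_SAMPLES`` are discarded — too short to cut a training
    window from, and padding would fabricate data. Each segment's time axis
    is rebased to start at 0.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) != len(values):
        raise CGMValidationError("times and values length mismatch")
    if len(times) == 0:
        return []
    if np.any(np.diff(times) <= 0):
        raise CGMValidationError("times must be strictly increasing")
    if max_gap is None:
        max_gap = 2.0 * sampling_period

    breaks = np.flatnonzero(np.diff(times) > max_gap) + 1
    segments: list[GlucoseSeries] = []
    for chunk_t, chunk_v in zip(np.split(times, breaks), np.split(values, breaks)):
        if len(chunk_t) < MIN_SEGMENT_SAMPLES:
            continue
        segments.append(
            GlucoseSeries(
                times=chunk_t - chunk_t[0],
                values=chunk_v,
                sampling_period=sampling_period,
                subject_id=subject_id,
            )
        )
    return segments


def split_first_n(
    series: GlucoseSeries, spec: SplitSpec
) -> tuple[GlucoseSeries, GlucoseSeries]:
    """Split off the first ``spec.n_test`` samples as the test set.

    Returns ``(test, train)``; concatenating them reproduces the input.
    """
    n = spec.n_test
    if n >= len(series):
        raise CGMValidationError(
            f"n_test={n} must be smaller than series length {len(series)}"
        )
    test = GlucoseSeries(
        times=series.times[:n] - series.times[0],
        values=series.values[:n],
        sampling_period=series.sampling_period,
        subject_id=series.subject_id,
    )
    train = GlucoseSeries(
        times=series.times[n:] - series.times[n],
        values=series.values[n:],
        sampling_period=series.sampling_period,
        subject_id=series.subject_id,
    )
    return test, train
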