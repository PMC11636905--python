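"""Seeded synthetic CGM generator.

Emulates the statistical shape of home-use CGM records from controlled
type-1 diabetic subjects — 5-minute sampling, 288 samples/day, readings
mostly between 3.5 and 15.5 mmol/L — as a sum of four components:

``value(t) = baseline + circadian sinusoid + meal pulses + AR(1) noise``

Meal excursions use a gamma-like pulse ``m * (dt/tau) * exp(1 - dt/tau)``
that rises over ~tau minutes and decays over a few tau, peaking at exactly
``m`` mmol/L above the ambient level at ``dt = tau``. Sensor noise is a
stationary AR(1) process (lag-1 correlation ``rho``, stationary standard
deviation ``sigma``), matching the strong short-lag correlation of CGM
sensor error. Values are clamped to the physiological/sensor range last.

The generator claims statistical resemblance (range, smoothness, meal
excursions, autocorrelated noise), not physiological fidelity: there is no
insulin dynamics, no glucose-insulin feedback, and no sensor drift or
calibration artefacts. Randomness comes from ``numpy``'s PCG64 generator,
so identical seeds give bit-identical series across platforms.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .timeseries_io import GlucoseSeries

SAMPLES_PER_DAY = 288
MINUTES_PER_DAY = 1440.0


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Synthetic CGM profile settings.

    ``meals`` is either an explicit list of ``(start_minute, magnitude
    mmol/L, tau minutes)`` tuples or None, in which case ``meals_per_day``
    meals are drawn per day at uniform random times with magnitude
    uniform in 2-6 mmol/L and tau uniform in 30-60 minutes. ``n_samples``
    overrides the ``days * 288`` length when set.
    """

    days: int = 2
    n_samples: int | None = None
    baseline: float = 7.0
    circadian_amplitude: float = 1.0
    meals: tuple[tuple[float, float, float], ...] | None = None
    meals_per_day: int = 3
    meal_magnitude_range: tuple[float, float] = (2.0, 6.0)
    meal_tau_range: tuple[float, float] = (30.0, 60.0)
    noise_rho: float = 0.8
    noise_sigma: float = 0.15
    clamp: tuple[float, float] = (2.2, 22.2)
    sampling_period: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days < 1 and self.n_samples is None:
            raise ValueError("days must be >= 1")
        if self.n_samples is not None and self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0.0 <= self.noise_rho < 1.0:
            raise ValueError("noise_rho must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not self.clamp[0] < self.clamp[1]:
            raise ValueError("clamp low must be below clamp high")

    @property
    def total_samples(self) -> int:
        if self.n_samples is not None:
            return self.n_samples
        return self.days * SAMPLES_PER_DAY


def meal_pulse(dt_minutes: np.ndarray, magnitude: float, tau: float) -> np.ndarray:
    """Gamma-like excursion kernel: 0 for dt < 0, peak ``magnitude`` at dt = tau."""
    dt = np.asarray(dt_minutes, dtype=float)
    out = np.zeros_like(dt)
    pos = dt >= 0
    out[pos] = magnitude * (dt[pos] / tau) * np.exp(1.0 - dt[pos] / tau)
    return out


def _ar1_noise(rng: np.random.Generator, n: int, rho: float, sigma: float) -> np.ndarray:
    """Stationary AR(1): e_t = rho e_{t-1} + eps_t, sd(e) = sigma."""
    if sigma == 0.0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sigma)
    innov_sd = sigma * np.sqrt(1.0 - rho**2)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + eps[t - 1]
    return e


def generate_profile(cfg: SimConfig) -> GlucoseSeries:
    """Generate one seeded synthetic CGM series at 5-minute sampling."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.total_samples
    t = np.arange(n) * cfg.sampling_period

    values = np.full(n, cfg.baseline)
    values += cfg.circadian_amplitude * np.sin(2.0 * np.pi * t / MINUTES_PER_DAY)

    if cfg.meals is not None:
        meals = list(cfg.meals)
    else:
        meals = []
        n_days = int(np.ceil((n * cfg.sampling_period) / MINUTES_PER_DAY))
        for day in range(n_days):
            for _ in range(cfg.meals_per_day):
                start = day * MINUTES_PER_DAY + rng.uniform(0.0, MINUTES_PER_DAY)
                mag = rng.uniform(*cfg.meal_magnitude_range)
                tau = rng.uniform(*cfg.meal_tau_range)
                meals.append((start, mag, tau))
    for start, mag, tau in meals:
        values += meal_pulse(t - start, mag, tau)

    values += _ar1_noise(rng, n, cfg.noise_rho, cfg.noise_sigma)
    values = np.clip(values, cfg.clamp[0], cfg.clamp[1])

    return GlucoseSeries(
        times=t,
        values=values,
        sampling_period=cfg.sampling_period,
        subject_id=f"sim-seed{cfg.seed}",
    )


def inject_gaps(
    series: GlucoseSeries,
    gap_starts: list[int],
    gap_lengths: list[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Delete the stated sample runs, returning raw (times, values) arrays
    with holes — the input expected by ``segment_by_gaps``.

    Gaps are (start index, length) pairs into the intact series; they must
    lie in range and not overlap. Remaining samples are unchanged.
    """
    if len(gap_starts) != len(gap_lengths):
        raise ValueError("gap_starts and gap_lengths length mismatch")
    n = len(series)
    spans = sorted(zip(gap_starts, gap_lengths))
    prev_end = -1
    drop = np.zeros(n, dtype=bool)
    for start, length in spans:
        if length < 1 or start < 0 or start + length > n:
            raise ValueError(f"gap ({start}, {length}) out of range for length {n}")
        if start <= prev_end:
            raise ValueError("overlapping gaps")
        prev_end = start + length - 1
        drop[start : start + length] = True
    keep = ~drop
    return series.times[keep].copy(), series.values[keep].copy()
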