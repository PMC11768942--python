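"""Synthetic test signals and acquisition-defect models.

Camera-based pulse measurement (remote photoplethysmography, rPPG) samples a
quasi-periodic cardiac waveform at a nominal frame rate, but real capture
pipelines drop frames and jitter the capture instants.  This module provides

* a dense (1 kHz) stand-in for the continuous waveform (:class:`DenseSignal`),
* generators for band-limited test sinusoids and pulse-like waveforms,
* the two corruption models used throughout the benchmarks: truncated-Gaussian
  timing jitter on a fraction of the capture instants, and uniform random
  sample loss.

Every stochastic operation is driven by an explicit seed so that corrupted
realizations are exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)

#: Default generation rate for the dense continuous-signal stand-in.
DEFAULT_GEN_RATE_HZ = 1000.0

#: Resting heart-rate frequency band (Hz); ~50-108 bpm.
RESTING_BAND_HZ = (0.8, 1.8)

#: Sinusoid amplitude that yields unit mean power.
UNIT_POWER_AMPLITUDE = float(np.sqrt(2.0))

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator, None]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DenseSignal:
    """High-rate waveform standing in for the continuous signal.

    Parameters
    ----------
    values : array-like
        Amplitudes on a regular lattice at ``rate_hz``.
    rate_hz : float
        Lattice rate in samples per second (default 1000).
    start_s : float
        Time of the first lattice point, in seconds.
    """

    values: np.ndarray
    rate_hz: float = DEFAULT_GEN_RATE_HZ
    start_s: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("DenseSignal.values must be a non-empty 1-D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("DenseSignal.values must be finite")
        if not (self.rate_hz > 0):
            raise ValueError("DenseSignal.rate_hz must be positive")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.start_s + np.arange(len(self.values)) / self.rate_hz

    def index_of(self, t: Union[float, np.ndarray]) -> np.ndarray:
        """Nearest lattice index of time(s) ``t``, clipped into range."""
        idx = np.rint((np.asarray(t, dtype=float) - self.start_s) * self.rate_hz)
        return np.clip(idx, 0, len(self.values) - 1).astype(np.int64)


@dataclass(frozen=True)
class SampledSeries:
    """Timestamped, possibly irregular/lossy observation sequence."""

    timestamps: np.ndarray
    values: np.ndarray
    nominal_rate_hz: Optional[float] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size or t.size < 1:
            raise ValueError(
                "timestamps and values must be 1-D arrays of equal length >= 1"
            )
        if not np.all(np.isfinite(t)):
            raise ValueError("timestamps must be finite")
        if np.any(np.diff(t) < 0):
            raise ValueError("timestamps must be sorted non-decreasing")
        if self.nominal_rate_hz is not None and not (self.nominal_rate_hz > 0):
            raise ValueError("nominal_rate_hz must be positive when given")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class UniformGrid:
    """Regular target timestamps t_i = start_s + i / rate_hz, i = 0..count-1."""

    start_s: float
    rate_hz: float
    count: int

    def __post_init__(self) -> None:
        if not (self.rate_hz > 0):
            raise ValueError("UniformGrid.rate_hz must be positive")
        if not (int(self.count) == self.count and self.count >= 1):
            raise ValueError("UniformGrid.count must be a positive integer")
        object.__setattr__(self, "count", int(self.count))

    @property
    def period_s(self) -> float:
        return 1.0 / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.count) / self.rate_hz


@dataclass(frozen=True)
class JitterSpec:
    """Truncated-Gaussian timing-bias model.

    A fraction ``irregular_ratio`` of capture instants receives a bias drawn
    from N(0, sigma_s^2) and clipped to [-max_bias_s, +max_bias_s].  When
    ``sigma_s`` / ``max_bias_s`` are omitted they default to the nominal
    sampling period at application time (40 ms at 25 Hz).
    """

    irregular_ratio: float
    sigma_s: Optional[float] = None
    max_bias_s: Optional[float] = None
    seed: SeedLike = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.irregular_ratio <= 1.0):
            raise ValueError("irregular_ratio must lie in [0, 1]")
        if self.sigma_s is not None and not (self.sigma_s > 0):
            raise ValueError("sigma_s must be positive when given")
        if self.max_bias_s is not None and not (self.max_bias_s > 0):
            raise ValueError("max_bias_s must be positive when given")


@dataclass(frozen=True)
class LossSpec:
    """Uniform random removal of ``loss_count`` samples (without replacement)."""

    loss_count: int
    seed: SeedLike = None

    def __post_init__(self) -> None:
        if not (int(self.loss_count) == self.loss_count and self.loss_count >= 0):
            raise ValueError("loss_count must be a non-negative integer")
        object.__setattr__(self, "loss_count", int(self.loss_count))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def make_sinusoid(
    freq_hz: float,
    phase_rad: float = 0.0,
    duration_s: float = 30.0,
    amplitude: float = UNIT_POWER_AMPLITUDE,
    rate_hz: float = DEFAULT_GEN_RATE_HZ,
    start_s: float = 0.0,
) -> DenseSignal:
    """Deterministic sinusoid A*sin(2*pi*f*t + phase) on the dense lattice."""
    if not (duration_s > 0):
        raise ValueError("duration_s must be positive")
    if not (freq_hz > 0):
        raise ValueError("freq_hz must be positive")
    n = int(round(duration_s * rate_hz))
    t = start_s + np.arange(n) / rate_hz
    return DenseSignal(
        amplitude * np.sin(2.0 * np.pi * freq_hz * t + phase_rad),
        rate_hz=rate_hz,
        start_s=start_s,
    )


def generate_sinusoid(
    duration_s: float = 30.0,
    band_hz: Sequence[float] = RESTING_BAND_HZ,
    amplitude: float = UNIT_POWER_AMPLITUDE,
    seed: SeedLike = None,
    rate_hz: float = DEFAULT_GEN_RATE_HZ,
) -> DenseSignal:
    """Random-frequency, random-phase sinusoid in a band.

    Frequency is drawn uniformly in ``band_hz`` and phase uniformly in
    [0, 2*pi) from the seeded generator.  The default amplitude sqrt(2)
    yields unit mean power.
    """
    f_lo, f_hi = float(band_hz[0]), float(band_hz[1])
    if not (0.0 < f_lo < f_hi):
        raise ValueError("band_hz must satisfy 0 < f_lo < f_hi")
    if not (duration_s > 0):
        raise ValueError("duration_s must be positive")
    if not (amplitude > 0):
        raise ValueError("amplitude must be positive")
    rng = _rng(seed)
    freq = rng.uniform(f_lo, f_hi)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    return make_sinusoid(freq, phase, duration_s, amplitude, rate_hz)


def generate_rppg_like(
    duration_s: float = 30.0,
    hr_bpm: float = 72.0,
    harmonic_ratio: float = 0.4,
    noise_sd: float = 0.15,
    wander_amp: float = 0.5,
    seed: SeedLike = None,
    rate_hz: float = DEFAULT_GEN_RATE_HZ,
    wander_freq_hz: float = 0.1,
) -> DenseSignal:
    """Pulse-like waveform with a known heart rate.

    Fundamental (amplitude 1) at ``hr_bpm / 60`` Hz, a second harmonic scaled
    by ``harmonic_ratio`` (the dicrotic-notch component of a PPG pulse),
    additive white Gaussian noise with standard deviation ``noise_sd`` and a
    slow baseline wander at ``wander_freq_hz`` (< 0.2 Hz, respiration-scale)
    of amplitude ``wander_amp``.  With ``harmonic_ratio < 1`` the spectral
    peak inside the resting band stays at the fundamental.
    """
    if not (hr_bpm > 0):
        raise ValueError("hr_bpm must be positive")
    if not (duration_s > 0):
        raise ValueError("duration_s must be positive")
    if min(harmonic_ratio, noise_sd, wander_amp) < 0:
        raise ValueError("harmonic_ratio, noise_sd and wander_amp must be >= 0")
    if not (0.0 < wander_freq_hz < 0.2):
        raise ValueError("wander_freq_hz must lie in (0, 0.2) Hz")
    rng = _rng(seed)
    f0 = hr_bpm / 60.0
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    ph0, ph1, phw = rng.uniform(0.0, 2.0 * np.pi, size=3)
    x = np.sin(2.0 * np.pi * f0 * t + ph0)
    x += harmonic_ratio * np.sin(2.0 * np.pi * 2.0 * f0 * t + ph1)
    x += wander_amp * np.sin(2.0 * np.pi * wander_freq_hz * t + phw)
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n)
    return DenseSignal(x, rate_hz=rate_hz, start_s=0.0)


# ---------------------------------------------------------------------------
# Sampling and corruption
# ---------------------------------------------------------------------------


def sample_regular(dense: DenseSignal, grid: UniformGrid) -> SampledSeries:
    """Read the dense lattice at the grid timestamps (ideal capture).

    The grid must lie within the dense signal's span; grid timestamps are
    assumed to fall on the dense lattice (25 Hz on a 1 kHz lattice does).
    """
    t = grid.times
    end = dense.start_s + (len(dense) - 1) / dense.rate_hz
    if t[0] < dense.start_s - 0.5 / dense.rate_hz or t[-1] > end + 0.5 / dense.rate_hz:
        raise ValueError("grid exceeds the dense signal's time span")
    idx = dense.index_of(t)
    return SampledSeries(t, dense.values[idx], nominal_rate_hz=grid.rate_hz)


def apply_timing_jitter(
    dense: DenseSignal, grid: UniformGrid, spec: JitterSpec
) -> SampledSeries:
    """Capture with timing bias on a random subset of grid instants.

    ``floor(ratio * count)`` grid indices (uniform, without replacement)
    receive a bias b ~ N(0, sigma^2) clipped to [-max_bias, +max_bias] and
    quantized onto the dense lattice.  A biased sample's value is the dense
    value at the biased instant and its logged timestamp records that
    (quantized) instant.  Output is sorted by timestamp, stable on the
    original capture index.
    """
    nominal = sample_regular(dense, grid)
    n = grid.count
    n_biased = int(np.floor(spec.irregular_ratio * n))
    if n_biased == 0:
        return nominal
    sigma = spec.sigma_s if spec.sigma_s is not None else grid.period_s
    max_bias = spec.max_bias_s if spec.max_bias_s is not None else grid.period_s
    rng = _rng(spec.seed)
    which = rng.choice(n, size=n_biased, replace=False)
    bias = np.clip(rng.normal(0.0, sigma, size=n_biased), -max_bias, max_bias)

    t = nominal.timestamps.copy()
    v = nominal.values.copy()
    idx = dense.index_of(t[which] + bias)
    t[which] = dense.start_s + idx / dense.rate_hz
    v[which] = dense.values[idx]
    order = np.argsort(t, kind="stable")
    return SampledSeries(t[order], v[order], nominal_rate_hz=grid.rate_hz)


def apply_sample_loss(series: SampledSeries, spec: LossSpec) -> SampledSeries:
    """Drop ``loss_count`` samples uniformly at random, keeping pairing/order."""
    n = len(series)
    if spec.loss_count >= n:
        raise ValueError(f"loss_count={spec.loss_count} must be < series length {n}")
    if spec.loss_count == 0:
        return series
    rng = _rng(spec.seed)
    drop = rng.choice(n, size=spec.loss_count, replace=False)
    keep = np.ones(n, dtype=bool)
    keep[drop] = False
    return SampledSeries(
        series.timestamps[keep], series.values[keep], series.nominal_rate_hz
    )
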