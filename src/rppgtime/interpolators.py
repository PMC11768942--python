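"""Timing-correction interpolators for irregular / lossy series.

Three low-complexity methods map a timestamped, possibly irregular or lossy
:class:`~rppgtime.synthesis.SampledSeries` onto a uniform grid:

``linear``
    Piecewise-linear interpolation between neighbouring samples.
``cubic``
    Natural cubic spline: per-interval cubics a(t-s)^3 + b(t-s)^2 + c(t-s) + d
    with continuous first and second derivatives at the knots and zero second
    derivative at both ends.
``cic``
    Cascaded integrator-comb (CIC) filter interpolation: the series is placed
    on a high-rate lattice (zero-stuffed, rate R times the grid rate), passed
    through N cascaded integrators, decimated onto the grid with the filter
    group delay compensated, and passed through N cascaded combs of delay M.
    A parallel occupancy channel (1 where a sample landed) runs through the
    same cascade and normalizes the output, which makes the filter gain
    self-compensating and lets the structure degrade gracefully when slots
    are empty.  The unnormalized cascade is the N-fold convolution of a
    boxcar of length R*M; it is multiplier-free, which is what makes CIC
    attractive on edge devices.

All three are linear operators in the sample values.  Outside the sampled
span every method clamps to the nearest computed value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

from .synthesis import SampledSeries, UniformGrid

logger = logging.getLogger(__name__)

METHODS = ("linear", "cubic", "cic")

# Input quantization for the fixed-point CIC path: 45 bits of input headroom
# leaves room for the (R*M)^N cascade gain inside int64 (45 + log2(20^4) < 63
# for the default configuration; checked at run time for others).
_CIC_QUANT_BITS = 45


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplineFit:
    """Piecewise cubic x_i(t) = a_i*dt^3 + b_i*dt^2 + c_i*dt + d_i, dt = t - s_i.

    ``knots`` are the (deduplicated, strictly increasing) sample timestamps
    s_1..s_n; ``coefficients`` has one (a, b, c, d) row per interval.
    """

    knots: np.ndarray
    coefficients: np.ndarray  # shape (n_knots - 1, 4)

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        coef = np.asarray(self.coefficients, dtype=float)
        if knots.ndim != 1 or len(knots) < 2:
            raise ValueError("SplineFit needs at least two knots")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("SplineFit knots must be strictly increasing")
        if coef.shape != (len(knots) - 1, 4):
            raise ValueError("coefficients must have shape (n_knots - 1, 4)")
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "coefficients", coef)


@dataclass(frozen=True)
class CICConfig:
    """CIC filter parameters: up/down factor R, cascade order N, comb delay M."""

    R: int = 10
    N: int = 4
    M: int = 2

    def __post_init__(self) -> None:
        for name in ("R", "N", "M"):
            v = getattr(self, name)
            if not (int(v) == v and v >= 1):
                raise ValueError(f"CICConfig.{name} must be a positive integer")
            object.__setattr__(self, name, int(v))

    @property
    def gain(self) -> int:
        """DC gain of the unnormalized cascade, (R*M)^N."""
        return (self.R * self.M) ** self.N

    @property
    def group_delay_hi(self) -> float:
        """Group delay in high-rate samples, N*(R*M - 1)/2."""
        return self.N * (self.R * self.M - 1) / 2.0


DEFAULT_CIC = CICConfig()


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------


def _collapse_duplicates(t: np.ndarray, v: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Average values sharing a timestamp so knots are strictly increasing."""
    tu, inverse, counts = np.unique(t, return_inverse=True, return_counts=True)
    if len(tu) == len(t):
        return t, v
    sums = np.zeros(len(tu))
    np.add.at(sums, inverse, v)
    return tu, sums / counts


def _validated_arrays(series: SampledSeries) -> Tuple[np.ndarray, np.ndarray]:
    t = np.asarray(series.timestamps, dtype=float)
    v = np.asarray(series.values, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
        raise ValueError("series contains non-finite entries")
    return t, v


# ---------------------------------------------------------------------------
# Linear interpolation
# ---------------------------------------------------------------------------


def linear_interpolate(series: SampledSeries, query_times: Sequence[float]) -> np.ndarray:
    """Piecewise-linear interpolation with clamped extrapolation.

    For s_i <= t < s_{i+1} returns
    x(s_i) + (x(s_{i+1}) - x(s_i)) / (s_{i+1} - s_i) * (t - s_i); outside the
    span, the nearest endpoint value.
    """
    t, v = _validated_arrays(series)
    t, v = _collapse_duplicates(t, v)
    if len(t) < 2:
        raise ValueError("linear interpolation needs >= 2 distinct timestamps")
    q = np.asarray(query_times, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("query times must be finite")
    return np.interp(q, t, v)


# ---------------------------------------------------------------------------
# Natural cubic spline
# ---------------------------------------------------------------------------


def fit_cubic_spline(series: SampledSeries) -> SplineFit:
    """Fit the natural cubic spline through the samples.

    Duplicate timestamps are collapsed by value-averaging first.  With fewer
    than 3 distinct samples the fit degrades to the linear interpolant (zero
    cubic/quadratic coefficients) with a logged warning.
    """
    t, v = _validated_arrays(series)
    t, v = _collapse_duplicates(t, v)
    if len(t) < 2:
        raise ValueError("spline fitting needs >= 2 distinct timestamps")
    if len(t) < 3:
        logger.warning(
            "fewer than 3 distinct samples: cubic spline falls back to linear"
        )
        slope = (v[1] - v[0]) / (t[1] - t[0])
        coef = np.array([[0.0, 0.0, slope, v[0]]])
        return SplineFit(t, coef)
    cs = CubicSpline(t, v, bc_type="natural")
    # CubicSpline.c is (4, n-1) with rows ordered cubic..constant in (t - s_i).
    return SplineFit(t, cs.c.T.copy())


def evaluate_spline(fit: SplineFit, query_times: Sequence[float]) -> np.ndarray:
    """Evaluate a piecewise cubic, clamping queries outside the knot span."""
    q = np.asarray(query_times, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("query times must be finite")
    knots = fit.knots
    qc = np.clip(q, knots[0], knots[-1])
    idx = np.clip(np.searchsorted(knots, qc, side="right") - 1, 0, len(knots) - 2)
    dt = qc - knots[idx]
    a, b, c, d = (fit.coefficients[idx, k] for k in range(4))
    return ((a * dt + b) * dt + c) * dt + d


# ---------------------------------------------------------------------------
# CIC filter interpolation
# ---------------------------------------------------------------------------


def _cic_cascade_decimate(
    x_hi: np.ndarray, count: int, offset: int, cfg: CICConfig
) -> np.ndarray:
    """Integrator cascade at the high rate, delay-compensated decimation,
    comb cascade at the low rate.  Exact int64 (two's-complement) arithmetic:
    integrator overflow wraps and is cancelled by the combs as long as the
    final output fits in 64 bits (Hogenauer register sizing).

    ``x_hi`` is int64 on the high-rate lattice; high-rate slot of grid point i
    is ``offset + i*R``.  Returns ``count`` comb-filtered low-rate samples.
    """
    R, N, M = cfg.R, cfg.N, cfg.M
    delay = int(round(cfg.group_delay_hi))
    y = x_hi
    with np.errstate(over="ignore"):
        for _ in range(N):
            y = np.cumsum(y)
        # Low-rate read positions, with N*M leading history points so the comb
        # cascade has real (not zero-padded) state at output index 0.
        m = np.arange(-N * M, count)
        pos = offset + delay + m * R
        z = y[pos]
        for _ in range(N):
            z = z[M:] - z[:-M]
    return z


def _cic_prepare(
    series: SampledSeries, grid: UniformGrid, cfg: CICConfig
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Slot assignment on the high-rate lattice.

    Returns (signal lattice with collision-averaged values, 0/1 occupancy
    lattice, offset of grid point 0 within the lattice arrays).
    """
    t, v = _validated_arrays(series)
    if len(t) == 0:
        raise ValueError("series must be non-empty")
    R, N, M = cfg.R, cfg.N, cfg.M
    f_hi = grid.rate_hz * R
    slots = np.rint((t - grid.start_s) * f_hi).astype(np.int64)
    delay = int(round(cfg.group_delay_hi))
    lo = min(int(slots.min()), delay - (N * M + 1) * R, 0)
    hi = max(int(slots.max()), (grid.count - 1) * R + delay)
    offset = -lo
    length = hi - lo + 1
    sums = np.zeros(length)
    counts = np.zeros(length)
    np.add.at(sums, slots + offset, v)
    np.add.at(counts, slots + offset, 1.0)
    occupied = counts > 0
    x_hi = np.zeros(length)
    x_hi[occupied] = sums[occupied] / counts[occupied]
    return x_hi, occupied.astype(np.int64), offset


def cic_raw(
    series: SampledSeries, grid: UniformGrid, cfg: CICConfig = DEFAULT_CIC
) -> Tuple[np.ndarray, np.ndarray]:
    """Unnormalized CIC responses (diagnostic).

    Returns the gain-uncorrected cascade output for the zero-stuffed signal
    lattice and for the occupancy indicator lattice, both decimated onto the
    grid with the group delay compensated.  ``cic_interpolate`` is their
    ratio wherever the occupancy response is positive.
    """
    x_hi, occ_hi, offset = _cic_prepare(series, grid, cfg)
    max_abs = float(np.max(np.abs(x_hi)))
    scale = 1.0 if max_abs == 0.0 else 2.0**_CIC_QUANT_BITS / max_abs
    if np.log2(max(cfg.gain, 1)) + _CIC_QUANT_BITS >= 63:
        raise ValueError(
            "CIC configuration gain too large for exact 64-bit arithmetic"
        )
    xq = np.rint(x_hi * scale).astype(np.int64)
    sig = _cic_cascade_decimate(xq, grid.count, offset, cfg).astype(float) / scale
    occ = _cic_cascade_decimate(occ_hi, grid.count, offset, cfg).astype(float)
    return sig, occ


def cic_interpolate(
    series: SampledSeries, grid: UniformGrid, cfg: CICConfig = DEFAULT_CIC
) -> np.ndarray:
    """CIC filter interpolation onto the grid with occupancy normalization.

    Wherever the occupancy response is positive the output is the ratio of
    the filtered signal to the filtered occupancy (which cancels the cascade
    gain (R*M)^N / R and re-weights partially filled windows); grid points
    whose filter window contains no sample are filled from the nearest valid
    output with a logged warning.
    """
    sig, occ = cic_raw(series, grid, cfg)
    valid = occ > 1e-9
    if not np.any(valid):
        raise ValueError("no CIC output window contains any sample")
    out = np.empty(grid.count)
    out[valid] = sig[valid] / occ[valid]
    if not np.all(valid):
        logger.warning(
            "CIC: %d of %d output windows empty; filled from nearest valid output",
            int(np.sum(~valid)),
            grid.count,
        )
        valid_idx = np.flatnonzero(valid)
        bad_idx = np.flatnonzero(~valid)
        pos = np.searchsorted(valid_idx, bad_idx)
        left = np.clip(pos - 1, 0, len(valid_idx) - 1)
        right = np.clip(pos, 0, len(valid_idx) - 1)
        use_right = np.abs(valid_idx[right] - bad_idx) < np.abs(
            bad_idx - valid_idx[left]
        )
        nearest = np.where(use_right, valid_idx[right], valid_idx[left])
        out[bad_idx] = out[nearest]
    return out


def cic_passband_gain(freq_hz: float, grid_rate_hz: float, cfg: CICConfig) -> float:
    """Magnitude response of the normalized cascade at ``freq_hz``.

    |sin(pi f R M / f_hi) / (R M sin(pi f / f_hi))|^N with f_hi = grid
    rate * R — the sinc-like droop of an N-fold boxcar of length R*M.
    Useful for predicting reconstruction error of band-limited signals.
    """
    f_hi = grid_rate_hz * cfg.R
    L = cfg.R * cfg.M
    x = np.pi * freq_hz / f_hi
    if x == 0.0:
        return 1.0
    return float(abs(np.sin(L * x) / (L * np.sin(x))) ** cfg.N)


# ---------------------------------------------------------------------------
# Dispatcher
# ---------------------------------------------------------------------------


def reconstruct(
    series: SampledSeries,
    grid: UniformGrid,
    method: str,
    cfg: Optional[CICConfig] = None,
) -> np.ndarray:
    """Reconstruct the series on the grid with the named method.

    ``method`` is one of ``linear``, ``cubic`` or ``cic``; ``cfg`` applies to
    ``cic`` only (defaults to R=10, N=4, M=2).  Returns ``grid.count`` values.
    """
    if method == "linear":
        return linear_interpolate(series, grid.times)
    if method == "cubic":
        return evaluate_spline(fit_cubic_spline(series), grid.times)
    if method == "cic":
        return cic_interpolate(series, grid, cfg or DEFAULT_CIC)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
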