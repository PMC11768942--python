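"""Heart-rate estimation from the corrected signal.

The estimation chain: average the green channel over a facial region of
interest (the green channel carries the strongest blood-volume signal),
timing-correct the resulting series onto a uniform grid, take the FFT
magnitude spectrum, and read the heart rate off the dominant frequency
inside the resting band (0.8-1.8 Hz).  With the standard 750-sample window
at a nominal 25 Hz the spectral resolution is 1/30 Hz, i.e. 2 bpm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .interpolators import CICConfig, reconstruct
from .synthesis import SampledSeries, UniformGrid

HR_METHODS = ("none", "linear", "cubic", "cic")


@dataclass(frozen=True)
class SpectrumBand:
    """Frequency band searched for the dominant peak (Hz)."""

    f_lo_hz: float = 0.8
    f_hi_hz: float = 1.8

    def __post_init__(self) -> None:
        if not (0.0 < self.f_lo_hz < self.f_hi_hz):
            raise ValueError("band must satisfy 0 < f_lo_hz < f_hi_hz")


DEFAULT_BAND = SpectrumBand()


@dataclass(frozen=True)
class HRResult:
    """Dominant frequency, heart rate, and the band-limited spectrum behind it."""

    hr_bpm: float
    f_peak_hz: float
    freqs_hz: np.ndarray
    magnitudes: np.ndarray


@dataclass(frozen=True)
class RoiBox:
    """Fractional rectangle (relative to frame height/width) in [0, 1]."""

    top: float
    bottom: float
    left: float
    right: float

    def __post_init__(self) -> None:
        ok = (
            0.0 <= self.top < self.bottom <= 1.0
            and 0.0 <= self.left < self.right <= 1.0
        )
        if not ok:
            raise ValueError("RoiBox requires 0 <= top < bottom <= 1 and likewise left/right")


def green_channel_mean(
    frame: np.ndarray, roi: RoiBox, channel_order: str = "bgr"
) -> float:
    """Mean of the green channel over the ROI pixels of one H x W x 3 frame.

    ``channel_order`` declares the frame's channel convention ("bgr" matches
    the common video-reader default, "rgb" image files).
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("frame must be an H x W x 3 array")
    order = channel_order.lower()
    if sorted(order) != ["b", "g", "r"]:
        raise ValueError("channel_order must be a permutation of 'rgb'")
    h, w = frame.shape[:2]
    r0, r1 = int(round(roi.top * h)), int(round(roi.bottom * h))
    c0, c1 = int(round(roi.left * w)), int(round(roi.right * w))
    if r1 <= r0 or c1 <= c0:
        raise ValueError("ROI rounds to zero pixels for this frame size")
    g = order.index("g")
    return float(np.mean(np.asarray(frame[r0:r1, c0:c1, g], dtype=float)))


def power_spectrum(
    values: Sequence[float], rate_hz: float
) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided FFT magnitude spectrum of a uniformly sampled window.

    The mean is removed; no taper window, no zero padding.  Frequencies are
    k * rate_hz / n for k = 0..floor(n/2); magnitudes are raw |DFT| values.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D array of >= 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if not (rate_hz > 0):
        raise ValueError("rate_hz must be positive")
    x = x - x.mean()
    mags = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / rate_hz)
    return freqs, mags


def estimate_hr(
    values: Sequence[float], rate_hz: float, band: SpectrumBand = DEFAULT_BAND
) -> HRResult:
    """Dominant-frequency heart rate inside the band.

    f_peak is the band-restricted argmax of the magnitude spectrum (ties
    broken toward the lowest frequency); hr_bpm = 60 * f_peak.
    """
    freqs, mags = power_spectrum(values, rate_hz)
    mask = (freqs >= band.f_lo_hz) & (freqs <= band.f_hi_hz)
    if not np.any(mask):
        raise ValueError("no FFT bin falls inside the band")
    bf = freqs[mask]
    bm = mags[mask]
    k = int(np.argmax(bm))  # argmax returns the first (= lowest-frequency) tie
    return HRResult(
        hr_bpm=60.0 * bf[k], f_peak_hz=float(bf[k]), freqs_hz=bf, magnitudes=bm
    )


def estimate_hr_from_series(
    series: SampledSeries,
    method: str,
    grid: UniformGrid,
    band: SpectrumBand = DEFAULT_BAND,
    cfg: Optional[CICConfig] = None,
) -> HRResult:
    """Full chain from a timestamped series to a heart rate.

    ``method="none"`` is the uncorrected baseline: the recorded values are
    treated as if they were uniform at the grid's nominal rate, timestamps
    ignored (the first ``grid.count`` values form the analysis window).
    This is exactly why sample loss shifts the dominant frequency: the
    surviving samples are compressed onto a too-short time axis.  Any other
    method reconstructs the series onto the grid first.
    """
    if method == "none":
        values = series.values[: grid.count]
    elif method in ("linear", "cubic", "cic"):
        values = reconstruct(series, grid, method, cfg)
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {HR_METHODS}")
    return estimate_hr(values, grid.rate_hz, band)
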