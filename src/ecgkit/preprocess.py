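"""Signal-quality gating and filtering ahead of QRS detection."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ConfigError

__all__ = ["QualityReport", "bandpass_filter", "quality_index"]

#: Detection band used both for filtering defaults and the quality score (Hz).
DEFAULT_BAND = (0.5, 40.0)
#: Variance below which a window is considered flat (mV^2).
FLATLINE_VAR = 1e-6
#: Fraction of samples pinned at the amplitude rails that flags clipping.
CLIP_FRACTION = 0.01
#: Quality score below which a segment is excluded from evaluation by default.
EXCLUDE_SCORE = 0.2


@dataclass
class QualityReport:
    """Quality assessment of one analysis window."""

    window_start: int
    window_end: int
    score: float
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ConfigError("quality score must lie in [0, 1]")

    @property
    def usable(self) -> bool:
        return self.score >= EXCLUDE_SCORE


def bandpass_filter(
    x: np.ndarray, fs: float, low: float = DEFAULT_BAND[0], high: float = DEFAULT_BAND[1]
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass.

    Applied forward-backward (`filtfilt`), so the output has no phase lag
    and the same length as the input.
    """
    x = np.asarray(x, dtype=np.float64)
    if not (0 <= low < high < fs / 2):
        raise ConfigError(f"band ({low}, {high}) Hz invalid for fs={fs} Hz")
    if x.size == 0:
        return x.copy()
    if low > 0:
        sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    else:
        sos = sps.butter(4, high, btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def quality_index(
    x: np.ndarray, fs: float, window_start: int = 0
) -> QualityReport:
    """Score a window of signal in [0, 1] and flag gross defects.

    The score is the in-band (0.5-40 Hz) fraction of total power of the
    mean-removed window, clamped to [0, 1]; it is therefore monotonically
    non-increasing in the out-of-band noise power fraction.  Flatline
    (variance < 1e-6 mV^2) and clipping (>= 1% of samples pinned at the
    window extremes while the range is non-trivial) zero the score.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2 * fs:
        raise ConfigError("quality window must be at least 2 s long")
    flags: set[str] = set()
    window_end = window_start + x.size

    if np.var(x) < FLATLINE_VAR:
        return QualityReport(window_start, window_end, 0.0, {"flatline"})

    rng_amp = x.max() - x.min()
    pinned = np.mean(x >= x.max() - 1e-9) + np.mean(x <= x.min() + 1e-9)
    if rng_amp > 0.5 and pinned >= CLIP_FRACTION:
        flags.add("clipping")

    xc = x - x.mean()
    freqs, psd = sps.welch(xc, fs=fs, nperseg=min(x.size, int(4 * fs)))
    total = float(np.trapezoid(psd, freqs))
    band = (freqs >= DEFAULT_BAND[0]) & (freqs <= DEFAULT_BAND[1])
    inband = float(np.trapezoid(psd[band], freqs[band])) if band.any() else 0.0
    score = 0.0 if total <= 0 else min(1.0, max(0.0, inband / total))
    if "clipping" in flags:
        score = 0.0
    if score < 0.5:
        flags.add("high_noise")
    return QualityReport(window_start, window_end, score, flags)
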