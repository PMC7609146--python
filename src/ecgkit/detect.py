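"""R-peak detection: Pan-Tompkins and an image-based CNN detector.

The classical detector follows the Pan-Tompkins stage sequence: 5-15 Hz
band-pass, five-point derivative, squaring, 150 ms moving-window
integration, dual adaptive thresholds with running signal/noise-level
estimates, a 200 ms refractory period, T-wave slope rejection within
360 ms, and RR-based search-back at 1.66x the running average RR.

The CNN path rasterizes short sliding windows of the one-dimensional
signal into small binary images and scores each window for containing a
centered QRS complex; the per-window probabilities are overlap-averaged
into a per-sample trace whose thresholded local maxima are the detections.
Both paths refine peaks to the local signal extremum within +/-50 ms.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import signal as sps

from . import nn
from .errors import ConfigError
from .io import AnnotationSet, EcgRecord

__all__ = [
    "DetectionResult",
    "CnnConfig",
    "pan_tompkins",
    "render_beat_image",
    "CnnDetector",
    "train_cnn_detector",
    "cnn_detect",
    "make_training_windows",
]

REFRACTORY_S = 0.200
REFINE_S = 0.050


@dataclass
class DetectionResult:
    """Detected R-peak sample positions with per-peak confidences."""

    record_name: str
    rpeaks: np.ndarray
    confidence: np.ndarray | None = None
    fs: float | None = None

    def __post_init__(self) -> None:
        self.rpeaks = np.asarray(self.rpeaks, dtype=np.int64)
        if self.confidence is None:
            self.confidence = np.ones(self.rpeaks.size)
        self.confidence = np.asarray(self.confidence, dtype=np.float64)
        if self.confidence.shape != self.rpeaks.shape:
            raise ConfigError("confidence must align with rpeaks")
        if self.rpeaks.size > 1 and np.any(np.diff(self.rpeaks) <= 0):
            raise ConfigError("rpeaks must be strictly ascending")
        if np.any((self.confidence < 0) | (self.confidence > 1)):
            raise ConfigError("confidences must lie in [0, 1]")
        if self.fs is not None and self.rpeaks.size > 1:
            if np.min(np.diff(self.rpeaks)) < REFRACTORY_S * self.fs:
                raise ConfigError("detections violate the 200 ms refractory period")

    def __len__(self) -> int:
        return self.rpeaks.size

    def to_annotations(self, symbol: str = "N") -> AnnotationSet:
        """Detections as an annotation set (placeholder beat symbol)."""
        return AnnotationSet(self.rpeaks, [symbol] * len(self))


def _refine_peaks(x: np.ndarray, peaks: np.ndarray, half: int) -> np.ndarray:
    """Move each peak to the extremum of |x - local median| within +/-half."""
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        seg = x[lo:hi]
        base = np.median(seg)
        refined.append(lo + int(np.argmax(np.abs(seg - base))))
    return np.asarray(refined, dtype=np.int64)


def _dedupe(peaks: np.ndarray, amp: np.ndarray, min_dist: int) -> np.ndarray:
    """Enforce the refractory spacing, keeping the larger-amplitude peak."""
    keep: list[int] = []
    for i, p in enumerate(peaks):
        if keep and p - peaks[keep[-1]] < min_dist:
            if amp[i] > amp[keep[-1]]:
                keep[-1] = i
        else:
            keep.append(i)
    return peaks[keep]


def pan_tompkins(x: np.ndarray, fs: float, record_name: str = "") -> DetectionResult:
    """Locate R peaks with the Pan-Tompkins adaptive-threshold detector."""
    x = np.asarray(x, dtype=np.float64)
    if fs < 100:
        raise ConfigError("pan_tompkins requires fs >= 100 Hz")
    if x.size < 2 * fs:
        raise ConfigError("pan_tompkins requires at least 2 s of signal")
    if np.ptp(x) == 0:
        return DetectionResult(record_name, np.array([], dtype=np.int64), fs=fs)

    # band-pass 5-15 Hz (zero-phase), derivative, square, integrate 150 ms
    sos = sps.butter(3, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    kern = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(bp, kern[::-1], mode="same")
    sq = deriv**2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return DetectionResult(record_name, np.array([], dtype=np.int64), fs=fs)

    # running signal / noise level estimates (learning phase: first 2 s)
    head = mwi[: int(2 * fs)]
    spki = float(head.max()) * 0.6
    npki = float(head.mean()) * 0.5
    slope_win = int(round(0.075 * fs))

    def max_slope(p: int) -> float:
        lo, hi = max(0, p - slope_win), min(deriv.size, p + slope_win + 1)
        return float(np.max(np.abs(deriv[lo:hi]))) if hi > lo else 0.0

    qrs: list[int] = []
    noise_cand: list[int] = []
    rr_hist: list[float] = []

    def thr1() -> float:
        return npki + 0.25 * (spki - npki)

    i = 0
    while i < cand.size:
        p = int(cand[i])
        a = float(mwi[p])
        accepted = False
        if a > thr1():
            if qrs and (p - qrs[-1]) < int(0.360 * fs):
                # possible T wave: reject if its slope is under half the last QRS slope
                if max_slope(p) < 0.5 * max_slope(qrs[-1]):
                    npki = 0.125 * a + 0.875 * npki
                    noise_cand.append(p)
                    i += 1
                    continue
            if not qrs or (p - qrs[-1]) >= refractory:
                accepted = True
        if accepted:
            if qrs:
                rr_hist.append(p - qrs[-1])
                rr_hist[:] = rr_hist[-8:]
            qrs.append(p)
            spki = 0.125 * a + 0.875 * spki
        else:
            npki = 0.125 * a + 0.875 * npki
            noise_cand.append(p)
            # search-back: have we overrun 1.66x the average RR without a beat?
            if qrs and rr_hist:
                rr_avg = float(np.mean(rr_hist))
                if (p - qrs[-1]) > 1.66 * rr_avg:
                    thr2 = 0.5 * thr1()
                    back = [
                        q
                        for q in noise_cand
                        if qrs[-1] + refractory <= q <= p and mwi[q] > thr2
                    ]
                    if back:
                        b = int(max(back, key=lambda q: mwi[q]))
                        rr_hist.append(b - qrs[-1])
                        rr_hist[:] = rr_hist[-8:]
                        qrs.append(b)
                        spki = 0.25 * float(mwi[b]) + 0.75 * spki
                        qrs.sort()
        i += 1

    peaks = np.asarray(sorted(qrs), dtype=np.int64)
    peaks = _refine_peaks(x, peaks, int(round(REFINE_S * fs)))
    peaks = np.unique(peaks)
    peaks = _dedupe(peaks, np.abs(x[peaks] - np.median(x)), refractory)
    return DetectionResult(record_name, peaks, fs=fs)


# ---------------------------------------------------------------------------
# Image rendering and the CNN detector
# ---------------------------------------------------------------------------

def render_beat_image(window: np.ndarray, height: int = 64, width: int = 64) -> np.ndarray:
    """Rasterize a 1-D window into a binary trace image.

    The time axis is resampled to ``width`` columns and the amplitude axis
    min-max scaled to rows (row 0 = maximum amplitude).  Each column holds
    the trace pixel; adjacent columns are connected by vertical fill so the
    trace is 4-connected.  A constant window renders at the middle row.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.size == 0:
        raise ConfigError("window must be non-empty")
    if height < 8 or width < 8:
        raise ConfigError("image must be at least 8x8")
    cols = np.interp(
        np.linspace(0, window.size - 1, width), np.arange(window.size), window
    )
    lo, hi = cols.min(), cols.max()
    if hi - lo < 1e-12:
        rows = np.full(width, height // 2, dtype=np.int64)
    else:
        rows = np.rint((hi - cols) / (hi - lo) * (height - 1)).astype(np.int64)
    img = np.zeros((height, width), dtype=np.uint8)
    img[rows, np.arange(width)] = 1
    for j in range(1, width):
        a, b = sorted((rows[j - 1], rows[j]))
        img[a : b + 1, j] = 1
    return img


@dataclass
class CnnConfig:
    """Architecture and training settings for the window-scoring CNN.

    Depth is configurable up to 32 convolution layers; the desk-scale
    default is 8 (3x3 kernels, stride-2 downsampling every second layer,
    global average pooling, two-way softmax head).
    """

    n_conv_layers: int = 8
    image_height: int = 64
    image_width: int = 64
    window: float = 0.25
    stride: float = 0.05
    epochs: int = 6
    learning_rate: float = 3e-3
    batch_size: int = 32
    base_channels: int = 4
    threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not (1 <= self.n_conv_layers <= 32):
            raise ConfigError("n_conv_layers must lie in [1, 32]")
        if self.window <= 0 or self.stride <= 0:
            raise ConfigError("window and stride must be positive")
        if self.image_height < 8 or self.image_width < 8:
            raise ConfigError("image must be at least 8x8")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ConfigError("invalid training settings")


def _build_net(cfg: CnnConfig, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    cin, ch = 1, cfg.base_channels
    spatial = min(cfg.image_height, cfg.image_width)
    for i in range(cfg.n_conv_layers):
        stride = 2 if (i % 2 == 1 and spatial > 4) else 1
        if stride == 2:
            spatial = (spatial - 1) // 2 + 1
        layers += [nn.Conv2d(cin, ch, stride, rng), nn.ReLU()]
        cin = ch
        if i % 2 == 1:
            ch = min(32, ch * 2)
    layers += [nn.GlobalAvgPool(), nn.Dense(cin, 2, rng)]
    return nn.Sequential(layers)


class CnnDetector:
    """A trained window classifier: P(window contains a centered QRS)."""

    def __init__(self, cfg: CnnConfig, fs: float):
        cfg.validate()
        self.cfg = cfg
        self.fs = fs
        rng = np.random.default_rng(cfg.seed)
        self.net = _build_net(cfg, rng)
        self.loss_history: list[float] = []
        self.trained = False

    # -- training ----------------------------------------------------------
    def fit(self, images: np.ndarray, labels: np.ndarray) -> "CnnDetector":
        images = np.asarray(images, dtype=np.float32)
        labels = np.asarray(labels, dtype=np.int64)
        if images.ndim == 3:
            images = images[:, None]
        classes = np.unique(labels)
        if classes.size < 2:
            raise ConfigError("training data must contain both classes")
        rng = np.random.default_rng(self.cfg.seed + 1)
        opt = nn.Adam(self.net.params(), lr=self.cfg.learning_rate)
        n = images.shape[0]
        for _ in range(self.cfg.epochs):
            order = rng.permutation(n)
            total = 0.0
            for s in range(0, n, self.cfg.batch_size):
                idx = order[s : s + self.cfg.batch_size]
                logits = self.net.forward(images[idx])
                loss, dlog = nn.softmax_xent(logits, labels[idx])
                self.net.backward(dlog.astype(np.float32))
                opt.step()
                total += loss * idx.size
            self.loss_history.append(total / n)
        self.trained = True
        return self

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """P(QRS-centered) per image."""
        if not self.trained:
            raise ConfigError("detector has not been trained")
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 3:
            images = images[:, None]
        out = []
        for s in range(0, images.shape[0], 256):
            logits = self.net.forward(images[s : s + 256])
            out.append(nn.softmax(logits)[:, 1])
        return np.concatenate(out) if out else np.zeros(0)

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | os.PathLike) -> None:
        """Save weights and config as a single .npz archive."""
        arrays = {
            f"p{i}": p for i, (p, _) in enumerate(self.net.params())
        }
        meta = json.dumps({"cfg": asdict(self.cfg), "fs": self.fs})
        np.savez(os.fspath(path), meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "CnnDetector":
        with np.load(os.fspath(path)) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            det = cls(CnnConfig(**meta["cfg"]), meta["fs"])
            for i, (p, _) in enumerate(det.net.params()):
                p[...] = z[f"p{i}"]
        det.trained = True
        return det


def make_training_windows(
    rec: EcgRecord,
    ann: AnnotationSet,
    cfg: CnnConfig,
    seed: int = 0,
    n_background_per_beat: float = 1.0,
    channel: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Build (images, labels) from a record with known R positions.

    Positive windows are centered on annotated beats; background windows
    are drawn uniformly at least 150 ms away from every beat.
    """
    rng = np.random.default_rng(seed)
    x = rec.signals[channel]
    half = int(round(cfg.window * rec.fs / 2))
    jitter = int(round(cfg.stride * rec.fs))  # cover every on-grid window near R
    beats = ann.beats().sample_indices
    images, labels = [], []
    for r in beats:
        c = int(r) + int(rng.integers(-jitter, jitter + 1))
        if c - half < 0 or c + half >= x.size:
            continue
        images.append(render_beat_image(x[c - half : c + half], cfg.image_height, cfg.image_width))
        labels.append(1)
    n_bg = int(round(len(images) * n_background_per_beat))
    margin = int(0.150 * rec.fs)
    tries = 0
    while n_bg > 0 and tries < 50 * n_bg:
        tries += 1
        c = int(rng.integers(half, x.size - half))
        if beats.size and np.min(np.abs(beats - c)) < margin:
            continue
        images.append(render_beat_image(x[c - half : c + half], cfg.image_height, cfg.image_width))
        labels.append(0)
        n_bg -= 1
    return np.asarray(images, dtype=np.float32), np.asarray(labels, dtype=np.int64)


def train_cnn_detector(
    dataset: tuple[np.ndarray, np.ndarray], cfg: CnnConfig, fs: float
) -> CnnDetector:
    """Train a window-scoring CNN on (images, labels in {0, 1})."""
    cfg.validate()
    images, labels = dataset
    return CnnDetector(cfg, fs).fit(images, labels)


def cnn_detect(
    rec: EcgRecord, model: CnnDetector, cfg: CnnConfig | None = None, channel: int = 0
) -> DetectionResult:
    """Slide, score and peak-pick the CNN probability trace over a record."""
    if not isinstance(model, CnnDetector) or not model.trained:
        raise ConfigError("cnn_detect needs a trained CnnDetector")
    cfg = cfg or model.cfg
    if model.fs and abs(rec.fs - model.fs) > 1e-9:
        raise ConfigError(f"record fs {rec.fs} differs from training fs {model.fs}")
    x = rec.signals[channel]
    fs = rec.fs
    half = int(round(cfg.window * fs / 2))
    step = max(1, int(round(cfg.stride * fs)))
    centers = np.arange(half, x.size - half, step, dtype=np.int64)
    if centers.size == 0:
        return DetectionResult(rec.record_name, np.array([], dtype=np.int64), fs=fs)
    images = np.stack(
        [
            render_beat_image(x[c - half : c + half], cfg.image_height, cfg.image_width)
            for c in centers
        ]
    ).astype(np.float32)
    probs = model.predict_proba(images)

    # overlap-average the window scores into a per-sample trace; each score
    # covers center +/- one stride so adjacent windows overlap twofold
    trace = np.zeros(x.size)
    counts = np.zeros(x.size)
    for c, p in zip(centers, probs):
        lo, hi = max(0, c - step), min(x.size, c + step)
        trace[lo:hi] += p
        counts[lo:hi] += 1
    trace = np.divide(trace, counts, out=np.zeros_like(trace), where=counts > 0)

    refractory = int(round(REFRACTORY_S * fs))
    peaks, _ = sps.find_peaks(trace, height=cfg.threshold, distance=refractory)
    peaks = _refine_peaks(x, peaks, int(round(REFINE_S * fs)))
    peaks = np.unique(peaks)
    conf_amp = trace[peaks]
    peaks = _dedupe(peaks, conf_amp, refractory)
    conf = np.clip(trace[peaks], 0.0, 1.0)
    return DetectionResult(rec.record_name, peaks, conf, fs=fs)
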