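"""Beat extraction and classification, AF detection, patient adaptation.

Beats are cut around detected R peaks (250 ms before to 400 ms after by
default) and described by the waveform resampled to 64 points plus three
timing/shape covariates (previous RR, next RR, QRS width), normalized per
record.  The primary classifier is a bidirectional LSTM over the beat
sequence, so each label sees both past and future context; logistic
regression and a linear-margin classifier serve as selectable baselines.

Atrial fibrillation is detected from RR irregularity alone: a sliding
window of intervals is flagged when the normalized successive-difference
statistic median(|dRR|)/median(RR) and the Shannon entropy of the binned
RR histogram both exceed their thresholds, and flagged windows are merged
into episodes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from . import nn
from .detect import DetectionResult
from .errors import ConfigError
from .io import EcgRecord

__all__ = [
    "BeatSegment",
    "RhythmEpisode",
    "LABELS",
    "extract_beats",
    "segments_to_features",
    "BiLstmBeatClassifier",
    "LogisticBeatClassifier",
    "LinearMarginBeatClassifier",
    "default_candidates",
    "classify_beat_sequence",
    "train_and_select",
    "detect_af",
    "adapt_to_patient",
    "select_ambiguous",
]

#: Classification alphabet: normal, ventricular ectopic, atrial ectopic.
LABELS = ("N", "V", "A")
_LABEL_TO_INT = {s: i for i, s in enumerate(LABELS)}

N_WAVEFORM_POINTS = 64


@dataclass
class BeatSegment:
    """One beat: waveform window around R plus timing covariates.

    ``rr_prev`` / ``rr_next`` are NaN at record edges; ``qrs_width`` is the
    contiguous span around R where |signal - baseline| stays above 25% of
    the R amplitude.
    """

    r_sample: int
    waveform: np.ndarray
    rr_prev: float
    rr_next: float
    qrs_width: float
    is_edge: bool = False


@dataclass
class RhythmEpisode:
    """A detected rhythm episode (currently AF only)."""

    kind: str
    start_sample: int
    end_sample: int
    mean_irregularity: float

    def __post_init__(self) -> None:
        if self.start_sample >= self.end_sample:
            raise ConfigError("episode start must precede end")


def _qrs_width(x: np.ndarray, r: int, fs: float) -> float:
    half = int(round(0.200 * fs))
    lo, hi = max(0, r - half), min(x.size, r + half + 1)
    seg = x[lo:hi]
    base = np.median(seg)
    amp = abs(x[r] - base)
    if amp <= 0:
        return 0.0
    above = np.abs(seg - base) >= 0.25 * amp
    c = r - lo
    a = c
    while a > 0 and above[a - 1]:
        a -= 1
    b = c
    while b < above.size - 1 and above[b + 1]:
        b += 1
    return (b - a + 1) / fs


def extract_beats(
    rec: EcgRecord,
    det: DetectionResult,
    pre_ms: float = 250.0,
    post_ms: float = 400.0,
    channel: int = 0,
) -> list[BeatSegment]:
    """Cut one fixed-length segment per detected peak.

    Edge beats are zero-padded and flagged; RR intervals at the record
    edges are NaN sentinels.
    """
    x = rec.signals[channel]
    fs = rec.fs
    pre = int(round(pre_ms / 1000.0 * fs))
    post = int(round(post_ms / 1000.0 * fs))
    peaks = det.rpeaks
    if peaks.size and (peaks.min() < 0 or peaks.max() >= x.size):
        raise ConfigError("detections outside record bounds")
    segments: list[BeatSegment] = []
    for i, r in enumerate(peaks):
        lo, hi = r - pre, r + post
        wave = np.zeros(pre + post)
        src_lo, src_hi = max(0, lo), min(x.size, hi)
        wave[src_lo - lo : src_hi - lo] = x[src_lo:src_hi]
        rr_prev = (r - peaks[i - 1]) / fs if i > 0 else float("nan")
        rr_next = (peaks[i + 1] - r) / fs if i < peaks.size - 1 else float("nan")
        segments.append(
            BeatSegment(
                r_sample=int(r),
                waveform=wave,
                rr_prev=rr_prev,
                rr_next=rr_next,
                qrs_width=_qrs_width(x, int(r), fs),
                is_edge=(lo < 0 or hi > x.size),
            )
        )
    return segments


def segments_to_features(segments: list[BeatSegment]) -> np.ndarray:
    """(n_beats, 67) feature matrix, normalized per record.

    Waveforms are resampled to 64 points and scaled by the record's median
    absolute R amplitude; RR intervals and QRS widths are scaled by their
    record medians (edge NaNs replaced by the median, i.e. ratio 1).
    """
    if not segments:
        return np.zeros((0, N_WAVEFORM_POINTS + 3))
    waves = np.stack(
        [
            np.interp(
                np.linspace(0, s.waveform.size - 1, N_WAVEFORM_POINTS),
                np.arange(s.waveform.size),
                s.waveform,
            )
            for s in segments
        ]
    )
    amp = np.median(np.max(np.abs(waves), axis=1))
    waves = waves / (amp if amp > 0 else 1.0)
    rr_prev = np.array([s.rr_prev for s in segments])
    rr_next = np.array([s.rr_next for s in segments])
    width = np.array([s.qrs_width for s in segments])
    rr_all = np.concatenate([rr_prev, rr_next])
    rr_med = np.nanmedian(rr_all) if np.isfinite(rr_all).any() else 1.0
    w_med = np.median(width[width > 0]) if (width > 0).any() else 1.0
    rr_prev = np.where(np.isfinite(rr_prev), rr_prev, rr_med) / rr_med
    rr_next = np.where(np.isfinite(rr_next), rr_next, rr_med) / rr_med
    width = width / w_med
    return np.column_stack([waves, rr_prev, rr_next, width]).astype(np.float64)


def labels_to_ints(labels) -> np.ndarray:
    out = []
    for s in labels:
        if s not in _LABEL_TO_INT:
            raise ConfigError(f"label {s!r} not in {LABELS}")
        out.append(_LABEL_TO_INT[s])
    return np.asarray(out, dtype=np.int64)


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

class BeatClassifier:
    """Interface: fit on feature sequences, emit per-beat probabilities."""

    name = "base"

    def __init__(self, seed: int = 0):
        self.seed = seed

    def reseed(self, seed: int) -> None:
        self.seed = seed

    def fit(self, seqs_x: list[np.ndarray], seqs_y: list[np.ndarray]) -> "BeatClassifier":
        raise NotImplementedError

    def predict_proba_seq(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict_seq(self, x: np.ndarray) -> np.ndarray:
        p = self.predict_proba_seq(x)
        return np.argmax(p, axis=1)

    def accuracy(self, seqs_x: list[np.ndarray], seqs_y: list[np.ndarray]) -> float:
        correct = total = 0
        for x, y in zip(seqs_x, seqs_y):
            pred = self.predict_seq(x)
            correct += int(np.sum(pred == y))
            total += y.size
        return correct / total if total else float("nan")


class BiLstmBeatClassifier(BeatClassifier):
    """Bidirectional LSTM over the beat sequence with a softmax head."""

    name = "bilstm"

    def __init__(
        self,
        hidden: int = 16,
        epochs: int = 30,
        learning_rate: float = 0.01,
        chunk: int = 128,
        seed: int = 0,
    ):
        super().__init__(seed)
        self.hidden = hidden
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.chunk = chunk
        self._net: tuple[nn.BiLSTM, nn.Dense] | None = None
        self.loss_history: list[float] = []

    def _init_net(self, din: int) -> None:
        rng = np.random.default_rng(self.seed)
        self._net = (nn.BiLSTM(din, self.hidden, rng), nn.Dense(2 * self.hidden, len(LABELS), rng))

    def _params(self):
        lstm, head = self._net
        return lstm.params() + head.params()

    def _chunks(self, seqs_x, seqs_y):
        for x, y in zip(seqs_x, seqs_y):
            for s in range(0, len(y), self.chunk):
                yield x[s : s + self.chunk], y[s : s + self.chunk]

    def _train(self, seqs_x, seqs_y, epochs: int, lr: float, shuffle_seed: int) -> None:
        opt = nn.Adam(self._params(), lr=lr)
        rng = np.random.default_rng(shuffle_seed)
        chunks = list(self._chunks(seqs_x, seqs_y))
        lstm, head = self._net
        for _ in range(epochs):
            order = rng.permutation(len(chunks))
            total = n_beats = 0.0
            for k in order:
                x, y = chunks[k]
                hs = lstm.forward(x.astype(np.float32))
                logits = head.forward(hs)
                loss, dlog = nn.softmax_xent(logits, y)
                lstm.backward(head.backward(dlog.astype(np.float32)))
                opt.step()
                total += loss * y.size
                n_beats += y.size
            self.loss_history.append(total / n_beats)

    def fit(self, seqs_x, seqs_y):
        seqs_y = [np.asarray(y, dtype=np.int64) for y in seqs_y]
        if not seqs_x:
            raise ConfigError("empty training set")
        self._init_net(seqs_x[0].shape[1])
        self.loss_history = []
        self._train(seqs_x, seqs_y, self.epochs, self.learning_rate, self.seed + 1)
        return self

    def adapt(self, x: np.ndarray, y: np.ndarray, seed: int, epochs: int = 4) -> None:
        """Fine-tune in place on one patient's labeled beats (low LR)."""
        if self._net is None:
            raise ConfigError("model must be trained before adaptation")
        self._train([x], [np.asarray(y, dtype=np.int64)], epochs, self.learning_rate * 0.3, seed)

    def predict_proba_seq(self, x: np.ndarray) -> np.ndarray:
        if self._net is None:
            raise ConfigError("model has not been trained")
        if len(x) == 0:
            return np.zeros((0, len(LABELS)))
        lstm, head = self._net
        out = []
        for s in range(0, len(x), self.chunk):
            hs = lstm.forward(x[s : s + self.chunk].astype(np.float32))
            out.append(nn.softmax(head.forward(hs)))
        return np.concatenate(out)


class _SklearnBeatClassifier(BeatClassifier):
    """Per-beat (context-free) baseline over stacked feature rows."""

    def _make(self):
        raise NotImplementedError

    def fit(self, seqs_x, seqs_y):
        x = np.concatenate(seqs_x)
        y = np.concatenate([np.asarray(v, dtype=np.int64) for v in seqs_y])
        self._clf = self._make()
        self._clf.fit(x, y)
        self._classes = self._clf.classes_
        return self

    def predict_proba_seq(self, x):
        if len(x) == 0:
            return np.zeros((0, len(LABELS)))
        if hasattr(self._clf, "predict_proba"):
            p = self._clf.predict_proba(x)
        else:
            d = self._clf.decision_function(x)
            if d.ndim == 1:
                d = np.column_stack([-d, d])
            p = nn.softmax(d)
        out = np.zeros((len(x), len(LABELS)))
        for k, c in enumerate(self._classes):
            out[:, int(c)] = p[:, k]
        return out


class LogisticBeatClassifier(_SklearnBeatClassifier):
    name = "logistic"

    def _make(self):
        return LogisticRegression(max_iter=500, random_state=self.seed)


class LinearMarginBeatClassifier(_SklearnBeatClassifier):
    name = "linear_margin"

    def _make(self):
        return LinearSVC(random_state=self.seed)


def default_candidates(seed: int = 0) -> list[tuple[str, BeatClassifier]]:
    """The model pool screened by :func:`train_and_select`."""
    return [
        ("bilstm", BiLstmBeatClassifier(seed=seed)),
        ("logistic", LogisticBeatClassifier(seed=seed)),
        ("linear_margin", LinearMarginBeatClassifier(seed=seed)),
    ]


def classify_beat_sequence(segments: list[BeatSegment], model: BeatClassifier) -> list[str]:
    """Label each beat N/V/A using a trained sequence classifier."""
    if not segments:
        return []
    x = segments_to_features(segments)
    return [LABELS[i] for i in model.predict_seq(x)]


def train_and_select(
    candidates: list[tuple[str, BeatClassifier]],
    train_set: tuple[list[np.ndarray], list[np.ndarray]],
    val_set: tuple[list[np.ndarray], list[np.ndarray]],
    seed: int = 0,
) -> tuple[str, BeatClassifier, pd.DataFrame]:
    """Train every candidate with a shared seed and pick the best.

    Returns (best name, best fitted model, leaderboard).  The winner is the
    argmax of validation accuracy; ties break toward the earlier candidate.
    """
    if not candidates:
        raise ConfigError("candidate list must not be empty")
    tr_x, tr_y = train_set
    va_x, va_y = val_set
    all_y = np.concatenate([np.asarray(y) for y in tr_y])
    if np.unique(all_y).size < 2:
        raise ConfigError("training set must contain at least two classes")
    rows = []
    fitted: list[BeatClassifier] = []
    for name, proto in candidates:
        model = copy.deepcopy(proto)
        model.reseed(seed)
        model.fit(tr_x, tr_y)
        acc = model.accuracy(va_x, va_y)
        rows.append({"name": name, "val_accuracy": acc})
        fitted.append(model)
    board = pd.DataFrame(rows)
    best_i = int(np.argmax(board["val_accuracy"].to_numpy()))
    return board.loc[best_i, "name"], fitted[best_i], board


# ---------------------------------------------------------------------------
# AF detection (RR-based)
# ---------------------------------------------------------------------------

AF_THETA1 = 0.08  # median(|dRR|) / median(RR)
AF_THETA2 = 0.7   # normalized Shannon entropy of the binned RR histogram
AF_BINS = 8
AF_WINDOW_BEATS = 30


def _window_stats(rr: np.ndarray, nbins: int) -> tuple[float, float]:
    med = float(np.median(rr))
    if med <= 0:
        return 0.0, 0.0
    drr = np.abs(np.diff(rr))
    irr = float(np.median(drr)) / med if drr.size else 0.0
    # fixed relative bin span: median +/- 37.5%
    edges = np.linspace(0.625 * med, 1.375 * med, nbins + 1)
    hist, _ = np.histogram(np.clip(rr, edges[0], edges[-1] - 1e-12), bins=edges)
    p = hist / hist.sum()
    p = p[p > 0]
    ent = float(-(p * np.log2(p)).sum()) / np.log2(nbins)
    return irr, ent


def detect_af(
    rr_series,
    window_beats: int = AF_WINDOW_BEATS,
    theta1: float = AF_THETA1,
    theta2: float = AF_THETA2,
    nbins: int = AF_BINS,
    r_samples=None,
) -> list[RhythmEpisode]:
    """Find AF episodes from RR irregularity.

    ``rr_series`` is in seconds (sampling-rate independent).  When the beat
    sample positions ``r_samples`` (length = len(rr)+1) are given, episode
    bounds are reported in samples of the source record; otherwise in
    cumulative-time units.  Fewer intervals than ``window_beats`` yields an
    empty result.
    """
    rr = np.asarray(rr_series, dtype=np.float64)
    if window_beats < 2:
        raise ConfigError("window_beats must be >= 2")
    if rr.size < window_beats:
        return []
    if r_samples is None:
        r_samples = np.concatenate([[0.0], np.cumsum(rr)])
    r_samples = np.asarray(r_samples)
    if r_samples.size != rr.size + 1:
        raise ConfigError("r_samples must have len(rr_series) + 1 entries")

    flagged = np.zeros(rr.size, dtype=bool)
    irr_of = np.full(rr.size, np.nan)
    for s in range(0, rr.size - window_beats + 1):
        w = rr[s : s + window_beats]
        irr, ent = _window_stats(w, nbins)
        if irr > theta1 and ent > theta2:
            flagged[s : s + window_beats] = True
            sl = slice(s, s + window_beats)
            irr_of[sl] = np.where(np.isnan(irr_of[sl]), irr, np.maximum(irr_of[sl], irr))

    episodes: list[RhythmEpisode] = []
    i = 0
    while i < rr.size:
        if not flagged[i]:
            i += 1
            continue
        j = i
        while j + 1 < rr.size and flagged[j + 1]:
            j += 1
        episodes.append(
            RhythmEpisode(
                kind="AF",
                start_sample=int(r_samples[i]),
                end_sample=int(r_samples[j + 1]),
                mean_irregularity=float(np.nanmean(irr_of[i : j + 1])),
            )
        )
        i = j + 1
    return episodes


# ---------------------------------------------------------------------------
# Patient adaptation and ambiguity queue
# ---------------------------------------------------------------------------

def adapt_to_patient(
    model: BeatClassifier,
    segments: list[BeatSegment],
    labels,
    seed: int = 0,
) -> BeatClassifier:
    """Fine-tune a copy of the model on one patient's first labeled beats.

    The base model is never modified.  The adapted copy is kept only if
    its accuracy on the adaptation set itself did not decrease; otherwise
    an unadapted copy is returned, so the post-condition holds regardless
    of fine-tuning dynamics.  An empty adaptation set returns the input
    model unchanged.
    """
    if not segments:
        return model
    x = segments_to_features(segments)
    y = labels_to_ints(labels)
    base = copy.deepcopy(model)
    adapted = copy.deepcopy(model)
    if hasattr(adapted, "adapt"):
        adapted.adapt(x, y, seed)
    else:
        adapted.fit([x], [y])
    acc_before = base.accuracy([x], [y])
    acc_after = adapted.accuracy([x], [y])
    return adapted if acc_after >= acc_before else base


def select_ambiguous(
    model: BeatClassifier, segments: list[BeatSegment], k: int
) -> list[BeatSegment]:
    """The k beats the classifier is least sure about (for referral).

    Ordered by ascending maximum class probability; ties break by
    ascending R position (stable).
    """
    if k < 0:
        raise ConfigError("k must be non-negative")
    if k > len(segments):
        raise ConfigError("k exceeds the number of segments")
    if k == 0 or not segments:
        return []
    x = segments_to_features(segments)
    conf = model.predict_proba_seq(x).max(axis=1)
    r = np.array([s.r_sample for s in segments])
    order = np.lexsort((r, conf))
    return [segments[i] for i in order[:k]]
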