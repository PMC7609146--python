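"""Beat-by-beat scoring in the AAMI / YY 0885 style.

Reference and test beat streams are matched one-to-one inside a tolerance
window (150 ms by default), and detection quality is reported as
sensitivity Se = TP/(TP+FN), positive predictivity P+ = TP/(TP+FP),
detection accuracy Acc = TP/(TP+FP+FN) and the F-measure
F_alpha = (1+alpha^2)*P+*Se / (alpha^2*P+ + Se).  Ventricular (V) and
supraventricular (S) ectopic-beat statistics are computed one-vs-rest on
the matched beats after mapping MIT-BIH symbols to the five AAMI classes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import AnnotationSet, BEAT_SYMBOLS

__all__ = [
    "MatchResult",
    "EvalMetrics",
    "DEFAULT_TOLERANCE_MS",
    "match_beats",
    "detection_metrics",
    "f_measure",
    "aami_map",
    "veb_sveb_stats",
    "per_record_report",
]

#: Matching window for beat-by-beat comparison, in milliseconds.
DEFAULT_TOLERANCE_MS = 150.0

_AAMI_MAP = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "F": "F",
    "/": "Q", "f": "Q", "Q": "Q",
}


@dataclass
class MatchResult:
    """Outcome of one-to-one beat matching."""

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ConfigError("tp/fp/fn must be non-negative")
        if self.pairs and len(self.pairs) != self.tp:
            raise ConfigError("tp must equal the number of matched pairs")

    @property
    def n_ref(self) -> int:
        return self.tp + self.fn

    @property
    def n_test(self) -> int:
        return self.tp + self.fp


@dataclass
class EvalMetrics:
    """Se / P+ / Acc / F bundle; undefined ratios are NaN, never silently 1."""

    se: float
    ppv: float
    acc: float
    f: float = float("nan")
    alpha: float = 1.0


def match_beats(ref, test, tolerance: float) -> MatchResult:
    """Greedy one-to-one matching of ascending beat positions.

    Reference beats are processed in ascending order; each takes the
    nearest still-unmatched test beat within ``tolerance`` samples, ties
    resolved toward the earlier test beat.
    """
    ref = np.asarray(ref, dtype=np.int64)
    test = np.asarray(test, dtype=np.int64)
    if tolerance < 0:
        raise ConfigError("tolerance must be non-negative")
    if ref.size > 1 and np.any(np.diff(ref) < 0):
        raise ConfigError("ref positions must be ascending")
    if test.size > 1 and np.any(np.diff(test) < 0):
        raise ConfigError("test positions must be ascending")

    matched = np.zeros(test.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for i, r in enumerate(ref):
        lo = int(np.searchsorted(test, r - tolerance, side="left"))
        hi = int(np.searchsorted(test, r + tolerance, side="right"))
        best = -1
        best_d = None
        for j in range(lo, hi):
            if matched[j]:
                continue
            d = abs(int(test[j]) - int(r))
            if best_d is None or d < best_d:  # ties keep the earlier beat
                best, best_d = j, d
        if best >= 0:
            matched[best] = True
            pairs.append((i, best))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=test.size - tp, fn=ref.size - tp, pairs=pairs)


def _safe_ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def detection_metrics(m: MatchResult, alpha: float = 1.0) -> EvalMetrics:
    """Se, P+ and Acc from a match, plus F_alpha when both ratios exist.

    When tp > 0, Acc = TP/(TP+FP+FN) coincides with (1/Se + 1/P+ - 1)^-1.
    """
    se = _safe_ratio(m.tp, m.tp + m.fn, "sensitivity")
    ppv = _safe_ratio(m.tp, m.tp + m.fp, "positive predictivity")
    acc = _safe_ratio(m.tp, m.tp + m.fp + m.fn, "accuracy")
    f = f_measure(se, ppv, alpha) if math.isfinite(se) and math.isfinite(ppv) else float("nan")
    return EvalMetrics(se=se, ppv=ppv, acc=acc, f=f, alpha=alpha)


def f_measure(se: float, ppv: float, alpha: float = 1.0) -> float:
    """F_alpha = (1+alpha^2) * P+ * Se / (alpha^2 * P+ + Se); F1 at alpha=1."""
    if alpha <= 0:
        raise ConfigError("alpha must be positive")
    if se == 0 and ppv == 0:
        return 0.0
    if not (0 <= se <= 1 and 0 <= ppv <= 1):
        raise ConfigError("se and ppv must lie in [0, 1]")
    return (1 + alpha**2) * ppv * se / (alpha**2 * ppv + se)


def aami_map(symbol: str) -> str:
    """Map a MIT-BIH beat symbol to its AAMI class (N, S, V, F or Q).

    VEB corresponds to class V, SVEB to class S.  Non-beat codes (rhythm
    marks, artifacts) are outside the domain and raise.
    """
    try:
        return _AAMI_MAP[symbol]
    except KeyError:
        raise ConfigError(f"{symbol!r} is not a beat symbol") from None


def veb_sveb_stats(
    ref: AnnotationSet,
    match: MatchResult,
    test_labels,
    classes: tuple[str, ...] = ("V", "S"),
) -> dict[str, EvalMetrics]:
    """One-vs-rest Se/P+ for the ectopic AAMI classes on matched beats.

    ``ref`` must contain only beat annotations (use ``ref.beats()``),
    matched against the test stream whose per-beat labels are
    ``test_labels`` (MIT-BIH symbols).  For each class, FN includes
    reference beats of that class left unmatched, and FP includes test
    beats labeled as the class but unmatched or matched to another class.
    """
    ref_cls = [aami_map(s) for s in ref.symbols]
    test_cls = [aami_map(s) for s in test_labels]
    if match.n_ref != len(ref_cls):
        raise ConfigError("match result does not correspond to ref annotations")
    if match.n_test != len(test_cls):
        raise ConfigError("match result does not correspond to test labels")
    out: dict[str, EvalMetrics] = {}
    for c in classes:
        tp = sum(1 for i, j in match.pairs if ref_cls[i] == c and test_cls[j] == c)
        fn = sum(1 for rc in ref_cls if rc == c) - tp
        fp = sum(1 for tc in test_cls if tc == c) - tp
        se = _safe_ratio(tp, tp + fn, f"class-{c} sensitivity")
        ppv = _safe_ratio(tp, tp + fp, f"class-{c} positive predictivity")
        acc = _safe_ratio(tp, tp + fp + fn, f"class-{c} accuracy")
        f = (
            f_measure(se, ppv, 1.0)
            if math.isfinite(se) and math.isfinite(ppv) and (se > 0 or ppv > 0)
            else float("nan")
        )
        out[c] = EvalMetrics(se=se, ppv=ppv, acc=acc, f=f, alpha=1.0)
    return out


def _round2(x: float) -> float:
    """Round to 2 decimals, halves away from zero (table convention)."""
    return math.floor(abs(x) * 100 + 0.5) / 100 * (1 if x >= 0 else -1)


def per_record_report(results: list[tuple[str, MatchResult]]) -> pd.DataFrame:
    """Per-record Se%/P+% table with a final row of column means.

    One row per record: total reference beats, Se and P+ as percentages
    rounded to two decimals (halves away from zero).  The ``Average`` row
    is the arithmetic mean of the per-record percentage columns, not a
    pooled-count recomputation.
    """
    if not results:
        raise ConfigError("per_record_report needs at least one record")
    rows = []
    for name, m in results:
        met = detection_metrics(m)
        rows.append(
            {
                "record": name,
                "total_beats": m.n_ref,
                "se_pct": _round2(met.se * 100) if math.isfinite(met.se) else float("nan"),
                "ppv_pct": _round2(met.ppv * 100) if math.isfinite(met.ppv) else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    avg = {
        "record": "Average",
        "total_beats": int(df["total_beats"].sum()),
        "se_pct": _round2(float(df["se_pct"].mean())),
        "ppv_pct": _round2(float(df["ppv_pct"].mean())),
    }
    return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)


def evaluate_record(
    ref: AnnotationSet,
    test_samples,
    fs: float,
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
) -> tuple[MatchResult, EvalMetrics]:
    """Convenience wrapper: match reference beats against detections."""
    beats = ref.beats(BEAT_SYMBOLS)
    tol = int(round(tolerance_ms / 1000.0 * fs))
    m = match_beats(beats.sample_indices, np.asarray(test_samples), tol)
    return m, detection_metrics(m)
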