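"""Beat extraction, sequence classification, AF detection, adaptation."""

from __future__ import annotations

import copy

import numpy as np
import pytest

from ecgkit import (
    DetectionResult,
    adapt_to_patient,
    classify_beat_sequence,
    detect_af,
    extract_beats,
    select_ambiguous,
    simulate_ecg,
    train_and_select,
)
from ecgkit.classify import (
    BiLstmBeatClassifier,
    LogisticBeatClassifier,
    default_candidates,
    labels_to_ints,
    segments_to_features,
)
from ecgkit.errors import ConfigError
from ecgkit.synth import SimConfig


# ---------------------------------------------------------------------------
# extract_beats
# ---------------------------------------------------------------------------

def test_one_segment_per_peak_fixed_length(nsr_record):
    rec, ann = nsr_record
    det = DetectionResult(rec.record_name, ann.sample_indices[:10], fs=rec.fs)
    segs = extract_beats(rec, det)
    assert len(segs) == 10
    expected_len = int(round(0.650 * rec.fs))
    assert all(s.waveform.size == expected_len for s in segs)


def test_edge_beat_padded_and_flagged(nsr_record):
    rec, _ = nsr_record
    det = DetectionResult(rec.record_name, np.array([int(0.05 * rec.fs)]), fs=rec.fs)
    (seg,) = extract_beats(rec, det, pre_ms=250)
    assert seg.is_edge
    n_pad = int(round(0.25 * rec.fs)) - int(0.05 * rec.fs)
    assert np.all(seg.waveform[:n_pad] == 0)


def test_pvc_widens_qrs(ectopy_record, ectopy_features):
    _, ann = ectopy_record
    segs, _, y = ectopy_features
    widths = np.array([s.qrs_width for s in segs])
    med_normal = np.median(widths[y == 0])
    v_widths = widths[y == 1]
    assert v_widths.size > 10
    assert np.median(v_widths) >= 1.5 * med_normal


# ---------------------------------------------------------------------------
# sequence classification and model selection
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted_bilstm(ectopy_features):
    segs, X, y = ectopy_features
    n_tr = int(0.7 * len(y))
    model = BiLstmBeatClassifier(seed=0)
    model.fit([X[:n_tr]], [y[:n_tr]])
    return model, n_tr


def test_bilstm_accuracy_on_separable_ectopy(ectopy_features, fitted_bilstm):
    segs, X, y = ectopy_features
    model, n_tr = fitted_bilstm
    assert len(y) >= 500
    assert model.accuracy([X[n_tr:]], [y[n_tr:]]) >= 0.95


def test_all_normal_record_labels(fitted_bilstm):
    rec, ann = simulate_ecg(SimConfig(duration=120, hr_mean=75, hr_sd=2, seed=21))
    det = DetectionResult(rec.record_name, ann.sample_indices, fs=rec.fs)
    segs = extract_beats(rec, det)
    model, _ = fitted_bilstm
    labels = classify_beat_sequence(segs, model)
    assert np.mean(np.array(labels) == "N") >= 0.98


def test_single_beat_sequence(fitted_bilstm, ectopy_features):
    segs, _, _ = ectopy_features
    model, _ = fitted_bilstm
    labels = classify_beat_sequence(segs[:1], model)
    assert len(labels) == 1 and labels[0] in "NVA"


def test_bilstm_uses_bidirectional_context(fitted_bilstm, ectopy_features):
    """Future beats influence labels: truncating the sequence after beat i
    can change beat i's probabilities."""
    _, X, _ = ectopy_features
    model, _ = fitted_bilstm
    full = model.predict_proba_seq(X[:40])
    half = model.predict_proba_seq(X[:20])
    assert not np.allclose(full[:20], half, atol=1e-6)


def test_train_and_select_bookkeeping(ectopy_features):
    segs, X, y = ectopy_features
    n = int(0.3 * len(y))
    cands = [
        ("logistic", LogisticBeatClassifier(seed=0)),
        ("bilstm", BiLstmBeatClassifier(epochs=3, seed=0)),
    ]
    name, model, board = train_and_select(
        cands, ([X[:n]], [y[:n]]), ([X[n : 2 * n]], [y[n : 2 * n]]), seed=0
    )
    assert list(board["name"]) == ["logistic", "bilstm"]
    assert name in {"logistic", "bilstm"}
    assert board["val_accuracy"].between(0, 1).all()


class _ConstantClassifier(LogisticBeatClassifier):
    name = "constant"

    def fit(self, seqs_x, seqs_y):
        return self

    def predict_proba_seq(self, x):
        out = np.zeros((len(x), 3))
        out[:, 2] = 1.0  # always 'A'
        return out


def test_constant_candidate_never_wins(ectopy_features):
    segs, X, y = ectopy_features
    n = int(0.3 * len(y))
    name, _, _ = train_and_select(
        [("constant", _ConstantClassifier(seed=0)), ("logistic", LogisticBeatClassifier(seed=0))],
        ([X[:n]], [y[:n]]),
        ([X[n : 2 * n]], [y[n : 2 * n]]),
        seed=0,
    )
    assert name == "logistic"


def test_selection_deterministic_and_permutation_safe(ectopy_features):
    segs, X, y = ectopy_features
    n = int(0.25 * len(y))
    tr, va = ([X[:n]], [y[:n]]), ([X[n : 2 * n]], [y[n : 2 * n]])
    cands = lambda: [
        ("logistic", LogisticBeatClassifier(seed=0)),
        ("bilstm", BiLstmBeatClassifier(epochs=3, seed=0)),
    ]
    _, _, b1 = train_and_select(cands(), tr, va, seed=0)
    _, _, b2 = train_and_select(cands(), tr, va, seed=0)
    assert b1.equals(b2)
    _, _, b3 = train_and_select(cands()[::-1], tr, va, seed=0)
    assert b3["val_accuracy"].max() == b1["val_accuracy"].max()


def test_empty_candidate_list_rejected(ectopy_features):
    _, X, y = ectopy_features
    with pytest.raises(ConfigError):
        train_and_select([], ([X], [y]), ([X], [y]), seed=0)


# ---------------------------------------------------------------------------
# AF detection
# ---------------------------------------------------------------------------

def test_constant_rr_no_episodes():
    assert detect_af(np.full(200, 0.8)) == []


def test_fewer_intervals_than_window_is_empty():
    assert detect_af(np.full(10, 0.8), window_beats=30) == []


def test_full_af_record_covered():
    rec, ann = simulate_ecg(
        SimConfig(duration=600, hr_mean=80, hr_sd=1,
                  af_segments=[(0.0, 600.0)], af_rr_cv=0.25, seed=13)
    )
    rr = np.diff(ann.sample_indices) / rec.fs
    eps = detect_af(rr, r_samples=ann.sample_indices)
    covered = sum(e.end_sample - e.start_sample for e in eps)
    span = ann.sample_indices[-1] - ann.sample_indices[0]
    assert covered >= 0.9 * span


def test_half_burden_jaccard():
    rec, ann = simulate_ecg(
        SimConfig(duration=600, hr_mean=80, hr_sd=1,
                  af_segments=[(150.0, 450.0)], af_rr_cv=0.25, seed=3)
    )
    rr = np.diff(ann.sample_indices) / rec.fs
    eps = detect_af(rr, r_samples=ann.sample_indices)
    truth = np.zeros(rec.n_samples, bool)
    truth[int(150 * rec.fs) : int(450 * rec.fs)] = True
    pred = np.zeros(rec.n_samples, bool)
    for e in eps:
        pred[e.start_sample : e.end_sample] = True
    jac = (truth & pred).sum() / (truth | pred).sum()
    assert jac >= 0.8


def test_af_burden_monotone_in_irregularity():
    """More RR irregularity never yields less detected AF burden."""
    for seed in (0, 1, 2):
        burdens = []
        for cv in (0.05, 0.15, 0.25, 0.35):
            rec, ann = simulate_ecg(
                SimConfig(duration=420, hr_mean=80, hr_sd=1,
                          af_segments=[(0.0, 420.0)], af_rr_cv=cv, seed=seed)
            )
            rr = np.diff(ann.sample_indices) / rec.fs
            eps = detect_af(rr, r_samples=ann.sample_indices)
            span = ann.sample_indices[-1] - ann.sample_indices[0]
            burdens.append(sum(e.end_sample - e.start_sample for e in eps) / span)
        assert all(a <= b + 1e-12 for a, b in zip(burdens, burdens[1:]))


# ---------------------------------------------------------------------------
# adaptation and the ambiguity queue
# ---------------------------------------------------------------------------

def test_empty_adaptation_set_returns_input_model(fitted_bilstm):
    model, _ = fitted_bilstm
    assert adapt_to_patient(model, [], []) is model


def test_adaptation_never_hurts_on_adaptation_set(fitted_bilstm):
    """Two-patient experiment: adapting on a shifted-morphology patient
    does not reduce accuracy on that patient's beats."""
    model, _ = fitted_bilstm
    cfg = SimConfig(duration=300, hr_mean=65, hr_sd=4, pvc_rate=0.15, seed=31)
    cfg.wave_params["R"].amplitude = 0.7
    cfg.wave_params["T"].amplitude = 0.45
    rec, ann = simulate_ecg(cfg)
    det = DetectionResult(rec.record_name, ann.sample_indices, fs=rec.fs)
    segs = extract_beats(rec, det)
    y = labels_to_ints(ann.symbols)
    n_adapt = sum(1 for s in segs if s.r_sample < 90 * rec.fs)  # leading window
    X = segments_to_features(segs)
    base_all = model.accuracy([X], [y])
    pre_adapt = model.accuracy([X[:n_adapt]], [y[:n_adapt]])
    pre_held = model.accuracy([X[n_adapt:]], [y[n_adapt:]])
    adapted = adapt_to_patient(model, segs[:n_adapt], ann.symbols[:n_adapt], seed=0)
    assert adapted.accuracy([X[:n_adapt]], [y[:n_adapt]]) >= pre_adapt
    assert adapted.accuracy([X[n_adapt:]], [y[n_adapt:]]) >= pre_held
    # base model untouched
    assert model.accuracy([X], [y]) == base_all


def test_adaptation_deterministic(fitted_bilstm, ectopy_features):
    model, _ = fitted_bilstm
    segs, X, y = ectopy_features
    a1 = adapt_to_patient(model, segs[:50], ["N"] * 50, seed=4)
    a2 = adapt_to_patient(model, segs[:50], ["N"] * 50, seed=4)
    assert np.allclose(a1.predict_proba_seq(X[:50]), a2.predict_proba_seq(X[:50]))


class _FixedConfidence:
    def __init__(self, probs):
        self._p = np.asarray(probs)

    def predict_proba_seq(self, x):
        return self._p


def test_select_ambiguous_picks_least_confident(ectopy_features):
    segs, _, _ = ectopy_features
    segs = segs[:3]
    probs = np.array([[0.99, 0.005, 0.005], [0.51, 0.25, 0.24], [0.80, 0.1, 0.1]])
    picked = select_ambiguous(_FixedConfidence(probs), segs, 1)
    assert picked[0].r_sample == segs[1].r_sample


def test_select_ambiguous_all_and_oracle_sort(ectopy_features, fitted_bilstm):
    segs, X, _ = ectopy_features
    model, _ = fitted_bilstm
    sub = segs[:40]
    out = select_ambiguous(model, sub, len(sub))
    assert len(out) == len(sub)
    conf = model.predict_proba_seq(segments_to_features(sub)).max(axis=1)
    oracle = [s.r_sample for _, s in sorted(zip(conf, sub), key=lambda t: (t[0], t[1].r_sample))]
    assert [s.r_sample for s in out] == oracle


def test_select_ambiguous_invalid_k(ectopy_features):
    segs, _, _ = ectopy_features
    with pytest.raises(ConfigError):
        select_ambiguous(_FixedConfidence(np.zeros((1, 3))), segs[:1], -1)
    with pytest.raises(ConfigError):
        select_ambiguous(_FixedConfidence(np.zeros((1, 3))), segs[:1], 2)
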