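"""Shared fixtures: synthetic records and trained models (session-scoped,
so the slow trainings run once)."""

from __future__ import annotations

import numpy as np
import pytest

from ecgkit import DetectionResult, extract_beats, simulate_ecg
from ecgkit.classify import labels_to_ints, segments_to_features
from ecgkit.detect import CnnConfig, make_training_windows, train_cnn_detector
from ecgkit.synth import SimConfig


@pytest.fixture(scope="session")
def nsr_record():
    """Clean normal sinus rhythm, 5 min at 360 Hz."""
    return simulate_ecg(SimConfig(duration=300, hr_mean=75, hr_sd=3, seed=1))


@pytest.fixture(scope="session")
def ectopy_record():
    """Mixed-rhythm fixture: ~10% PVC, ~10% PAC over 7 minutes."""
    return simulate_ecg(
        SimConfig(duration=420, hr_mean=80, hr_sd=2, pvc_rate=0.1, pac_rate=0.1, seed=0)
    )


@pytest.fixture(scope="session")
def ectopy_features(ectopy_record):
    """(segments, X, y) using ground-truth R positions."""
    rec, ann = ectopy_record
    det = DetectionResult(rec.record_name, ann.sample_indices, fs=rec.fs)
    segments = extract_beats(rec, det)
    return segments, segments_to_features(segments), labels_to_ints(ann.symbols)


@pytest.fixture(scope="session")
def trained_cnn():
    """Window-scoring CNN trained on a clean 4-minute record."""
    rec, ann = simulate_ecg(SimConfig(duration=240, hr_mean=80, hr_sd=3, seed=0))
    cfg = CnnConfig(seed=0)
    images, labels = make_training_windows(rec, ann, cfg, seed=0)
    rng = np.random.default_rng(1)
    order = rng.permutation(len(labels))
    n_tr = int(0.8 * len(labels))
    model = train_cnn_detector((images[order[:n_tr]], labels[order[:n_tr]]), cfg, rec.fs)
    holdout = (images[order[n_tr:]], labels[order[n_tr:]])
    return model, holdout
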