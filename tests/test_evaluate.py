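"""Beat matching, detection metrics, AAMI classes, report tables."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgkit import (
    AnnotationSet,
    MatchResult,
    aami_map,
    detection_metrics,
    f_measure,
    match_beats,
    per_record_report,
    veb_sveb_stats,
)
from ecgkit.errors import ConfigError


def oracle_max_matching(ref, test, tol):
    """Maximum-cardinality bipartite matching within tolerance."""
    g = nx.Graph()
    g.add_nodes_from((f"r{i}" for i in range(len(ref))))
    g.add_nodes_from((f"t{j}" for j in range(len(test))))
    for i, r in enumerate(ref):
        for j, t in enumerate(test):
            if abs(r - t) <= tol:
                g.add_edge(f"r{i}", f"t{j}")
    m = nx.bipartite.maximum_matching(g, top_nodes=[f"r{i}" for i in range(len(ref))])
    return sum(1 for k in m if k.startswith("r"))


# ---------------------------------------------------------------------------
# match_beats
# ---------------------------------------------------------------------------

def test_match_simple_pairs():
    m = match_beats([100, 500], [105, 495], 54)
    assert (m.tp, m.fp, m.fn) == (2, 0, 0)
    assert oracle_max_matching([100, 500], [105, 495], 54) == 2


def test_match_empty_ref():
    m = match_beats([], [100], 54)
    assert (m.tp, m.fp, m.fn) == (0, 1, 0)


def test_match_prefers_nearest_candidate():
    """ref 100 against test {60, 130}: 130 is nearer (30 vs 40)."""
    m = match_beats([100], [60, 130], 54)
    assert (m.tp, m.fp, m.fn) == (1, 1, 0)
    assert m.pairs == [(0, 1)]


def test_match_tie_takes_earlier_test_beat():
    m = match_beats([100], [90, 110], 54)
    assert m.pairs == [(0, 0)]


@settings(max_examples=100, derandomize=True)
@given(
    st.lists(st.integers(0, 1000), max_size=8),
    st.lists(st.integers(0, 1000), max_size=8),
    st.integers(0, 80),
)
def test_match_count_conservation(ref, test, tol):
    """tp+fp = |test| and tp+fn = |ref| for arbitrary inputs."""
    ref, test = sorted(ref), sorted(test)
    m = match_beats(ref, test, tol)
    assert m.tp + m.fp == len(test)
    assert m.tp + m.fn == len(ref)
    assert m.tp == len(m.pairs)
    # one-to-one
    assert len({i for i, _ in m.pairs}) == m.tp
    assert len({j for _, j in m.pairs}) == m.tp


def test_greedy_equals_optimal_when_spacing_exceeds_twice_tolerance():
    """On spaced instances, greedy matching is maximum-cardinality."""
    rng = np.random.default_rng(0)
    tol = 54
    checked = 0
    for _ in range(300):
        n_ref, n_test = rng.integers(0, 7, size=2)
        ref = np.sort(rng.choice(np.arange(0, 1000), size=n_ref, replace=False))
        test = np.sort(rng.choice(np.arange(0, 1000), size=n_test, replace=False))
        spaced = (np.all(np.diff(ref) > 2 * tol) if n_ref > 1 else True) and (
            np.all(np.diff(test) > 2 * tol) if n_test > 1 else True
        )
        if not spaced:
            continue
        checked += 1
        assert match_beats(ref, test, tol).tp == oracle_max_matching(ref, test, tol)
    assert checked >= 50


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_perfect_detection_metrics():
    met = detection_metrics(MatchResult(100, 0, 0))
    assert met.se == met.ppv == met.acc == 1.0


def test_metric_arithmetic():
    met = detection_metrics(MatchResult(8, 1, 1))
    assert met.se == pytest.approx(8 / 9)
    assert met.ppv == pytest.approx(8 / 9)
    assert met.acc == pytest.approx(0.8)


def test_acc_matches_inverse_identity():
    """Acc = (1/Se + 1/P+ - 1)^-1 reproduces a published module row."""
    se, ppv = 0.9953, 0.9995
    acc = 1.0 / (1.0 / se + 1.0 / ppv - 1.0)
    assert acc == pytest.approx(0.9948, abs=5e-4)


def test_undefined_ratios_are_nan_with_warning():
    with pytest.warns(UserWarning):
        met = detection_metrics(MatchResult(0, 0, 0))
    assert math.isnan(met.se) and math.isnan(met.ppv)


def test_f_measure_published_anchors():
    assert f_measure(0.9953, 0.9908, 1) == pytest.approx(0.9931, abs=5e-4)
    assert f_measure(0.9814, 0.9710, 1) == pytest.approx(0.9762, abs=5e-4)
    assert f_measure(1.0, 1.0, 2.5) == 1.0


def test_f_measure_zero_convention_and_validation():
    assert f_measure(0.0, 0.0, 1.0) == 0.0
    with pytest.raises(ConfigError):
        f_measure(0.5, 0.5, 0.0)


def test_f_alpha_weighting_moves_toward_se():
    """Large alpha weights recall; small alpha weights precision."""
    se, ppv = 0.9, 0.6
    assert f_measure(se, ppv, 10.0) > f_measure(se, ppv, 1.0) > f_measure(se, ppv, 0.1)


# ---------------------------------------------------------------------------
# AAMI classes
# ---------------------------------------------------------------------------

def test_aami_map_is_total_over_beat_alphabet():
    from ecgkit.io import BEAT_SYMBOLS

    expected = {"V": "V", "E": "V", "A": "S", "a": "S", "J": "S", "S": "S", "F": "F"}
    for sym in BEAT_SYMBOLS:
        cls = aami_map(sym)
        assert cls in "NSVFQ"
        if sym in expected:
            assert cls == expected[sym]
    with pytest.raises(ConfigError):
        aami_map("+")


def test_veb_sveb_from_constructed_confusion():
    """Hand-computed one-vs-rest ratios from a small confusion layout."""
    ref = AnnotationSet(np.arange(1, 10) * 100,
                        ["N", "N", "N", "V", "V", "V", "A", "A", "N"])
    test_syms = ["N", "N", "V", "V", "V", "N", "A", "N", "N"]
    m = match_beats(ref.sample_indices, ref.sample_indices, 10)
    stats = veb_sveb_stats(ref, m, test_syms)
    # V: tp=2 (idx 3,4), fn=1 (idx 5), fp=1 (idx 2)
    assert stats["V"].se == pytest.approx(2 / 3)
    assert stats["V"].ppv == pytest.approx(2 / 3)
    # S: tp=1 (idx 6), fn=1 (idx 7), fp=0
    assert stats["S"].se == pytest.approx(1 / 2)
    assert stats["S"].ppv == pytest.approx(1.0)


def test_veb_perfect_and_all_normal(ectopy_record):
    _, ann = ectopy_record
    beats = ann.beats()
    m = match_beats(beats.sample_indices, beats.sample_indices, 10)
    perfect = veb_sveb_stats(beats, m, beats.symbols)
    assert perfect["V"].se == 1.0 and perfect["V"].ppv == 1.0
    with pytest.warns(UserWarning):
        all_n = veb_sveb_stats(beats, m, ["N"] * len(beats))
    assert all_n["V"].se == 0.0


def test_missing_class_gives_nan_se():
    ref = AnnotationSet(np.array([100, 200]), ["N", "N"])
    m = match_beats(ref.sample_indices, ref.sample_indices, 10)
    with pytest.warns(UserWarning):
        stats = veb_sveb_stats(ref, m, ["N", "N"])
    assert math.isnan(stats["V"].se)


# ---------------------------------------------------------------------------
# per-record report
# ---------------------------------------------------------------------------

def test_single_perfect_record_report():
    df = per_record_report([("r1", MatchResult(100, 0, 0))])
    assert list(df["se_pct"]) == [100.0, 100.0]
    assert list(df["ppv_pct"]) == [100.0, 100.0]
    assert df.iloc[-1]["record"] == "Average"


def test_average_row_is_mean_of_percentages():
    results = [("a", MatchResult(90, 0, 10)), ("b", MatchResult(100, 0, 0))]
    df = per_record_report(results)
    assert df.iloc[-1]["se_pct"] == pytest.approx(95.00)


def test_report_percentages_round_trip():
    df = per_record_report([("a", MatchResult(997, 2, 3))])
    txt = df.to_csv(index=False)
    import io as _io

    import pandas as pd

    back = pd.read_csv(_io.StringIO(txt))
    assert back["se_pct"].equals(df["se_pct"])
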