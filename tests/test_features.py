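"""Extrema counting and per-window feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pushpull.exceptions import ValidationError
from pushpull.features import (
    PeakParams,
    extract_emg_features,
    extract_force_features,
    extract_time_features,
    find_local_extrema,
)
from pushpull.segmentation import Phase, SubSegment, make_subsegment

from oracles import brute_force_extrema


def _phase(start, middle, end, label="P1-2-3"):
    return Phase(1, label, start, middle, end)


def test_monotone_series_has_no_extrema():
    assert find_local_extrema(np.linspace(0, 1, 200), 100.0) == []


def test_constant_series_has_no_extrema():
    assert find_local_extrema(np.ones(50), 100.0) == []


@pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
def test_sine_extrema_counts_match_bruteforce(k):
    fs = 100.0
    t = np.arange(int(k * fs)) / fs  # k periods of a 1 Hz sine
    x = np.sin(2 * np.pi * t)
    found = find_local_extrema(x, fs)
    n_max = sum(1 for e in found if e.kind == "max")
    n_min = sum(1 for e in found if e.kind == "min")
    assert n_max == k
    oracle = brute_force_extrema(x, fs)
    assert [(e.index, e.kind) for e in found] == [(i, kind) for i, kind, _ in oracle]
    assert abs(n_max - n_min) <= 1


def test_extrema_match_bruteforce_on_random_windows():
    """Fast path vs the O(n^2) definition-based oracle, random windows."""
    rng = np.random.default_rng(2024)
    for _ in range(30):
        n = int(rng.integers(10, 800))
        x = np.cumsum(rng.normal(size=n)) + rng.normal(0, 0.3, n)
        found = find_local_extrema(x, 100.0)
        oracle = brute_force_extrema(x, 100.0)
        assert [(e.index, e.kind) for e in found] == [(i, kind) for i, kind, _ in oracle]


@given(st.integers(0, 2**31 - 1), st.floats(0.0, 0.2), st.floats(0.0, 0.3))
@settings(max_examples=25)
def test_extrema_alternate(seed, prom, sep):
    rng = np.random.default_rng(seed)
    x = np.cumsum(rng.normal(size=300))
    params = PeakParams(prominence_fraction=prom, min_separation=sep)
    found = find_local_extrema(x, 100.0, params)
    kinds = [e.kind for e in found]
    assert all(a != b for a, b in zip(kinds, kinds[1:]))
    n_max = kinds.count("max")
    n_min = kinds.count("min")
    assert abs(n_max - n_min) <= 1


def test_extrema_too_short_window():
    with pytest.raises(ValidationError, match="3"):
        find_local_extrema([1.0, 2.0], 100.0)


def test_force_features_constant_window():
    fs = 100.0
    phase = _phase(0.0, 5.0, 10.0)  # window [3.5, 8.5]
    sub = make_subsegment(phase)
    feats = extract_force_features(np.full(1001, 4.0), sub, fs)
    assert feats.mean == pytest.approx(4.0)
    assert feats.sd == 0.0
    assert feats.max == feats.min == 4.0
    assert feats.integral == pytest.approx(4.0 * 5.0)  # level x window duration
    assert feats.n_local_maxima == feats.n_local_minima == 0
    assert feats.max_consecutive_extremum_diff == 0.0


def test_force_features_linear_ramp_window():
    """F(t) = t on a [0, 1] window: trapezoid integral exactly 0.5 and the
    maximum at the window end (relative moment +1)."""
    fs = 100.0
    phase = _phase(-0.7, 0.3, 1.3)  # sub-segment window is exactly [0, 1]
    sub = make_subsegment(phase)
    assert (sub.t_a, sub.t_b) == pytest.approx((0.0, 1.0))
    t = np.arange(201) / fs
    feats = extract_force_features(t, sub, fs)
    assert feats.integral == pytest.approx(0.5, abs=1e-12)
    assert feats.rel_moment_max == pytest.approx(1.0)
    assert feats.rel_moment_min == pytest.approx(-1.0)
    assert feats.mean == pytest.approx(0.5)


def test_force_feature_equivariance_under_scaling():
    rng = np.random.default_rng(7)
    fs = 100.0
    phase = _phase(0.0, 4.0, 9.0)
    sub = make_subsegment(phase)
    f = 2.0 + np.abs(np.cumsum(rng.normal(size=1000))) / 10
    a = extract_force_features(f, sub, fs)
    b = extract_force_features(3.0 * f, sub, fs)
    for name in ("mean", "sd", "max", "min", "integral", "max_consecutive_extremum_diff"):
        assert getattr(b, name) == pytest.approx(3.0 * getattr(a, name), rel=1e-9)
    assert b.n_local_maxima == a.n_local_maxima
    assert b.n_local_minima == a.n_local_minima
    assert b.rel_moment_max == a.rel_moment_max
    assert b.rel_moment_min == a.rel_moment_min


def test_trapezoid_integral_against_closed_form_sine():
    fs = 100.0
    phase = _phase(-0.7, 0.3, 1.3)  # window [0, 1]
    sub = make_subsegment(phase)
    t = np.arange(201) / fs
    feats = extract_force_features(2.0 + np.sin(2 * np.pi * t), sub, fs)
    exact = 2.0  # integral of 2 + sin(2 pi t) over one period
    assert feats.integral == pytest.approx(exact, abs=1e-4)  # O(dt^2) accuracy


def test_mean_times_duration_close_to_integral(small_session):
    from pushpull.segmentation import build_phases
    from pushpull.signals import force_magnitude

    f = force_magnitude(
        small_session.force["fxR"], small_session.force["fyR"], small_session.force["fzR"]
    )
    grp = small_session.events[small_session.events["traversal"] == 1]
    phase = build_phases(grp, traversal_index=1)[0]
    sub = make_subsegment(phase)
    feats = extract_force_features(f, sub, small_session.sample_rate)
    window = sub.t_b - sub.t_a
    assert feats.integral == pytest.approx(feats.mean * window, rel=0.02)


def test_time_features():
    tf = extract_time_features(_phase(0.0, 10.0, 20.0))
    assert tf.overall_duration == 20.0
    assert tf.position_related_task_time == 10.0
    tf = extract_time_features(_phase(0.0, 9.0, 17.7))
    assert tf.overall_duration == pytest.approx(17.7)
    assert tf.position_related_task_time == pytest.approx(9.0)
    assert tf.rel_moment_middle == 0.0


def test_emg_features_per_channel():
    fs = 100.0
    phase = _phase(0.0, 5.0, 10.0)
    sub = make_subsegment(phase)
    n = 1001
    channels = {name: np.full(n, 0.3) for name in (
        "back_left", "back_right", "chest_left", "chest_right", "arm_left", "arm_right")}
    feats = extract_emg_features(channels, sub, fs)
    assert all(v == pytest.approx(0.3) for v in feats.values())
    zeros = {name: np.zeros(n) for name in channels}
    assert all(v == 0.0 for v in extract_emg_features(zeros, sub, fs).values())
    del channels["arm_left"]
    with pytest.raises(ValidationError, match="arm_left"):
        extract_emg_features(channels, sub, fs)
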