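"""Percent differences, group aggregation and report assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pushpull.cohort import GroupLabel
from pushpull.compare import (
    EMG_REPORT_ROWS,
    FORCE_REPORT_ROWS,
    REPORT_ROWS,
    aggregate_group,
    build_report,
    percent_diff,
    render_report,
    series_contrast,
)
from pushpull.exceptions import ValidationError


def _features(values_by_participant, parameter="force_mean_right", traversals=(1,)):
    rows = []
    for pid, value in values_by_participant.items():
        for trav in traversals:
            rows.append(
                {
                    "participant": pid,
                    "traversal": trav,
                    "phase": "P1-2-3",
                    "parameter": parameter,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


def test_percent_diff_worked_examples():
    assert percent_diff(292.9955, 554.118) == pytest.approx(89.12169, abs=1e-3)
    assert percent_diff(264.0737, 553.0317) == pytest.approx(109.4232, abs=1e-3)
    assert percent_diff(7.0, 7.0) == 0.0
    with pytest.raises(ValidationError, match="zero reference"):
        percent_diff(0.0, 1.0)


@given(st.floats(0.01, 1e6), st.floats(0.01, 1e6))
def test_percent_diff_antisymmetric_in_sign(a, b):
    if a != b:
        assert np.sign(percent_diff(a, b)) == -np.sign(percent_diff(b, a))


def test_aggregate_group_pools_cells():
    feats = pd.concat(
        [
            _features({1: 2.0, 2: 4.0}),
            _features({3: 10.0}),
        ],
        ignore_index=True,
    )
    labels = {1: GroupLabel.GROUP1, 2: GroupLabel.GROUP1, 3: GroupLabel.GROUP2}
    agg = aggregate_group(feats, labels)
    assert agg.loc["force_mean_right", "group1_mean"] == 3.0
    assert agg.loc["force_mean_right", "group2_mean"] == 10.0
    assert agg.loc["force_mean_right", "n_group1"] == 2


def test_aggregate_requires_labels_and_nonempty_groups():
    feats = _features({1: 2.0})
    with pytest.raises(ValidationError, match="without a group label"):
        aggregate_group(feats, {})
    with pytest.raises(ValidationError, match="GROUP2"):
        aggregate_group(feats, {1: GroupLabel.GROUP1})


def test_aggregate_invariant_to_row_order_and_relabeling():
    feats = _features({1: 2.0, 2: 4.0, 3: 9.0})
    labels = {1: GroupLabel.GROUP1, 2: GroupLabel.GROUP1, 3: GroupLabel.GROUP2}
    a = aggregate_group(feats, labels)
    shuffled = feats.sample(frac=1.0, random_state=0)
    b = aggregate_group(shuffled, labels)
    pd.testing.assert_frame_equal(a, b)
    # swapping ids within a group changes nothing
    swapped = feats.replace({"participant": {1: 2, 2: 1}})
    c = aggregate_group(swapped, labels)
    pd.testing.assert_frame_equal(a, c)


def test_series_contrast_examples():
    traversals = tuple(range(1, 11))
    flat = _features({1: 5.0, 2: 5.0}, traversals=traversals)
    labels = {1: GroupLabel.GROUP1, 2: GroupLabel.GROUP2}
    res = series_contrast(flat, labels)
    assert res.loc["force_mean_right", "pct_diff_s910_vs_s12_group1"] == 0.0

    rows = []
    for trav in traversals:
        value = 8.0 if trav in (9, 10) else 10.0
        rows.append(
            {
                "participant": 1,
                "traversal": trav,
                "phase": "P1-2-3",
                "parameter": "x",
                "value": value,
            }
        )
        rows.append({**rows[-1], "participant": 2})
    res = series_contrast(pd.DataFrame(rows), labels)
    assert res.loc["x", "pct_diff_s910_vs_s12_group1"] == pytest.approx(-20.0)

    with pytest.raises(ValidationError, match="missing"):
        series_contrast(_features({1: 1.0, 2: 1.0}, traversals=(1, 2)), labels)


def _aggregates_from(reference: pd.DataFrame, rows) -> pd.DataFrame:
    mapping = dict(rows)
    return pd.DataFrame(
        {
            "group1_mean": {mapping[label]: reference.loc[label, "group1_mean"] for label in mapping},
            "group2_mean": {mapping[label]: reference.loc[label, "group2_mean"] for label in mapping},
        }
    )


def test_report_reproduces_published_contrast_columns():
    """Feeding the published group means through percent_diff recovers the
    published percent-difference column within the input-rounding bound."""
    from pushpull.datasets import load_reference_group_means

    for kind, rows in (("force", FORCE_REPORT_ROWS), ("emg", EMG_REPORT_ROWS)):
        ref = load_reference_group_means(kind)
        report = build_report(_aggregates_from(ref, rows), rows=rows)
        dev = (report["pct_diff_g2_vs_g1"] - ref["pct_diff_g2_vs_g1"]).abs()
        assert dev.max() <= 0.05
    force = load_reference_group_means("force")
    rep = build_report(_aggregates_from(force, FORCE_REPORT_ROWS), rows=FORCE_REPORT_ROWS)
    assert rep.loc["Fmaxright", "pct_diff_g2_vs_g1"] == pytest.approx(-0.48757, abs=0.01)
    emg = load_reference_group_means("emg")
    rep = build_report(_aggregates_from(emg, EMG_REPORT_ROWS), rows=EMG_REPORT_ROWS)
    assert rep.loc["EMGMAVback_left", "pct_diff_g2_vs_g1"] == pytest.approx(411.02, abs=0.05)


def test_report_zero_when_groups_equal():
    agg = pd.DataFrame(
        {"group1_mean": {"x": 3.0, "y": 5.0}, "group2_mean": {"x": 3.0, "y": 5.0}}
    )
    rows = (("X", "x"), ("Y", "y"))
    report = build_report(agg, rows=rows)
    assert (report["pct_diff_g2_vs_g1"] == 0.0).all()
    assert list(report.index) == ["X", "Y"]


def test_report_missing_parameter_is_named():
    agg = pd.DataFrame({"group1_mean": {"x": 1.0}, "group2_mean": {"x": 2.0}})
    with pytest.raises(ValidationError, match="'y'"):
        build_report(agg, rows=(("X", "x"), ("Y", "y")))


def test_report_internal_consistency_and_order(small_config):
    """Percent columns recompute from their own mean columns to 1e-9."""
    from dataclasses import replace

    from pushpull.pipeline import analyze_participant
    from pushpull.simulate import simulate_cohort

    records, sessions = simulate_cohort(
        1, 1, small_config, replace(small_config, effort_scale=1.5), seed=11
    )
    tables = []
    for pid, sp in sessions.items():
        t = analyze_participant(sp.recording, sp.mvc_trials)
        t.insert(0, "participant", pid)
        tables.append(t)
    feats = pd.concat(tables, ignore_index=True)
    labels = {1: GroupLabel.GROUP1, 2: GroupLabel.GROUP2}
    report = build_report(
        aggregate_group(feats, labels),
        series_contrast(feats, labels, early=(1,), late=(2,)),
    )
    assert list(report.index) == [label for label, _ in REPORT_ROWS]
    recomputed = (
        (report["group2_mean"] - report["group1_mean"]) / report["group1_mean"] * 100
    )
    np.testing.assert_allclose(report["pct_diff_g2_vs_g1"], recomputed, rtol=1e-9)
    for g in ("group1", "group2"):
        rec = (
            (report[f"s910_{g}_mean"] - report[f"s12_{g}_mean"])
            / report[f"s12_{g}_mean"]
            * 100
        )
        np.testing.assert_allclose(report[f"pct_diff_s910_vs_s12_{g}"], rec, rtol=1e-9)
    text = render_report(report)
    assert "Fintright" in text and "EMGMAVarm_left" in text
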