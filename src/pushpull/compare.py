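"""Group aggregation, percent-difference contrasts and report tables.

Two descriptive contrasts are reported per parameter, mirroring the
study's result tables: the percent difference of the high-score group's
mean versus the low-score group's (Group 2 vs Group 1), and -- within
each group -- the percent difference of the last two traversals versus
the first two (S9-10 vs S1-2), which gauges within-session drift.  No
inferential statistics are computed: the design reports percent
differences only.

The percent difference is always ``(value - reference) / reference * 100``
with Group 1 (or S1-2) as the reference.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import GroupLabel
from .exceptions import ValidationError

__all__ = [
    "FORCE_REPORT_ROWS",
    "EMG_REPORT_ROWS",
    "REPORT_ROWS",
    "percent_diff",
    "aggregate_group",
    "series_contrast",
    "build_report",
    "render_report",
]

#: (display label, internal parameter name), in the fixed report order
FORCE_REPORT_ROWS: tuple[tuple[str, str], ...] = (
    ("Fmeanright", "force_mean_right"),
    ("Fmeanleft", "force_mean_left"),
    ("Fstdright", "force_std_right"),
    ("Fstdleft", "force_std_left"),
    ("Fmaxright", "force_max_right"),
    ("Fmaxleft", "force_max_left"),
    ("Fminright", "force_min_right"),
    ("Fminleft", "force_min_left"),
    ("Fintright", "force_integral_right"),
    ("Fintleft", "force_integral_left"),
    ("relative moment of Fmaxright", "force_rel_moment_max_right"),
    ("relative moment of Fmaxleft", "force_rel_moment_max_left"),
    ("relative moment of Fminright", "force_rel_moment_min_right"),
    ("relative moment of Fminleft", "force_rel_moment_min_left"),
    ("maximal difference of consecutive extremums right", "force_max_consec_extremum_diff_right"),
    ("maximal difference of consecutive extremums left", "force_max_consec_extremum_diff_left"),
    ("number of local maxima right", "force_n_local_maxima_right"),
    ("number of local maxima left", "force_n_local_maxima_left"),
    ("number of local minima right", "force_n_local_minima_right"),
    ("number of local minima left", "force_n_local_minima_left"),
    ("position-related task time", "position_related_task_time"),
    ("overall duration", "overall_duration"),
)

EMG_REPORT_ROWS: tuple[tuple[str, str], ...] = (
    ("EMGMAVback_right", "emg_mav_back_right"),
    ("EMGMAVback_left", "emg_mav_back_left"),
    ("EMGMAVchest_right", "emg_mav_chest_right"),
    ("EMGMAVchest_left", "emg_mav_chest_left"),
    ("EMGMAVarm_right", "emg_mav_arm_right"),
    ("EMGMAVarm_left", "emg_mav_arm_left"),
)

REPORT_ROWS = FORCE_REPORT_ROWS + EMG_REPORT_ROWS


def percent_diff(reference: float, value: float) -> float:
    """``(value - reference) / reference * 100`` (reference must be non-zero)."""
    if reference == 0:
        raise ValidationError("percent difference is undefined for a zero reference")
    return (value - reference) / reference * 100.0


def _norm_labels(labels: Mapping[int, GroupLabel | str]) -> dict[int, str]:
    return {int(k): GroupLabel(v).value for k, v in labels.items()}


def _check_features(features: pd.DataFrame) -> None:
    required = {"participant", "traversal", "phase", "parameter", "value"}
    missing = required - set(features.columns)
    if missing:
        raise ValidationError(f"features table is missing columns: {sorted(missing)}")


def _grouped(features: pd.DataFrame, labels: Mapping[int, GroupLabel | str]) -> pd.DataFrame:
    labels = _norm_labels(labels)
    unknown = set(features["participant"].unique()) - set(labels)
    if unknown:
        raise ValidationError(f"participants without a group label: {sorted(unknown)}")
    out = features.copy()
    out["group"] = out["participant"].map(labels)
    return out[out["group"].isin([GroupLabel.GROUP1.value, GroupLabel.GROUP2.value])]


def aggregate_group(
    features: pd.DataFrame,
    labels: Mapping[int, GroupLabel | str],
    per_participant_first: bool = False,
) -> pd.DataFrame:
    """Group means per parameter.

    Default weighting pools every (participant, traversal, phase) cell
    with equal weight; ``per_participant_first`` averages within each
    participant before averaging participants (sensitivity option).
    Returns a frame indexed by internal parameter name with columns
    ``group1_mean``, ``group2_mean``, ``n_group1``, ``n_group2``.
    """
    _check_features(features)
    df = _grouped(features, labels)
    for g in (GroupLabel.GROUP1.value, GroupLabel.GROUP2.value):
        if not (df["group"] == g).any():
            raise ValidationError(f"no feature values for {g}")
    if per_participant_first:
        df = (
            df.groupby(["group", "parameter", "participant"], as_index=False)["value"]
            .mean()
        )
    means = df.groupby(["parameter", "group"])["value"].agg(["mean", "count"]).unstack("group")
    out = pd.DataFrame(
        {
            "group1_mean": means[("mean", GroupLabel.GROUP1.value)],
            "group2_mean": means[("mean", GroupLabel.GROUP2.value)],
            "n_group1": means[("count", GroupLabel.GROUP1.value)].astype(int),
            "n_group2": means[("count", GroupLabel.GROUP2.value)].astype(int),
        }
    )
    out.index.name = "parameter"
    return out


def series_contrast(
    features: pd.DataFrame,
    labels: Mapping[int, GroupLabel | str],
    early: tuple[int, int] = (1, 2),
    late: tuple[int, int] = (9, 10),
) -> pd.DataFrame:
    """Within-group drift: percent difference of late vs early traversals.

    Returns a frame indexed by parameter with, per group, the early/late
    means and ``pct_diff`` = percent_diff(early mean, late mean).
    """
    _check_features(features)
    df = _grouped(features, labels)
    present = set(df["traversal"].unique())
    needed = set(early) | set(late)
    if not needed <= present:
        raise ValidationError(
            f"series contrast needs traversals {sorted(needed)}; missing "
            f"{sorted(needed - present)}"
        )
    out = {}
    for gname, gkey in ((GroupLabel.GROUP1.value, "group1"), (GroupLabel.GROUP2.value, "group2")):
        sub = df[df["group"] == gname]
        e = sub[sub["traversal"].isin(early)].groupby("parameter")["value"].mean()
        l = sub[sub["traversal"].isin(late)].groupby("parameter")["value"].mean()
        out[f"s12_{gkey}_mean"] = e
        out[f"s910_{gkey}_mean"] = l
        out[f"pct_diff_s910_vs_s12_{gkey}"] = pd.Series(
            {p: percent_diff(e[p], l[p]) for p in e.index if e[p] != 0}
        )
    res = pd.DataFrame(out)
    res.index.name = "parameter"
    return res


def build_report(
    aggregates: pd.DataFrame,
    contrasts: pd.DataFrame | None = None,
    rows: tuple[tuple[str, str], ...] = REPORT_ROWS,
) -> pd.DataFrame:
    """Assemble the fixed-order comparison table.

    Rows follow the canonical report order; columns are the two group
    means, the Group 2 vs Group 1 percent difference, and (when
    ``contrasts`` is given) the per-group S9-10 vs S1-2 percent
    differences with their underlying means.  Every percent column is
    recomputed here from its own mean columns, so the table is
    internally consistent by construction.
    """
    records = []
    for label, param in rows:
        if param not in aggregates.index:
            raise ValidationError(f"aggregates are missing parameter {param!r} ({label})")
        g1 = float(aggregates.loc[param, "group1_mean"])
        g2 = float(aggregates.loc[param, "group2_mean"])
        rec = {
            "parameter": label,
            "group1_mean": g1,
            "group2_mean": g2,
            "pct_diff_g2_vs_g1": percent_diff(g1, g2),
        }
        if contrasts is not None:
            if param not in contrasts.index:
                raise ValidationError(f"contrasts are missing parameter {param!r} ({label})")
            for gkey in ("group1", "group2"):
                e = float(contrasts.loc[param, f"s12_{gkey}_mean"])
                l = float(contrasts.loc[param, f"s910_{gkey}_mean"])
                rec[f"s12_{gkey}_mean"] = e
                rec[f"s910_{gkey}_mean"] = l
                rec[f"pct_diff_s910_vs_s12_{gkey}"] = percent_diff(e, l)
        records.append(rec)
    return pd.DataFrame(records).set_index("parameter")


def render_report(report: pd.DataFrame, decimals: int = 6) -> str:
    """Aligned plain-text rendering (values rounded; CSV keeps full precision)."""
    display_cols = [
        c
        for c in (
            "group1_mean",
            "group2_mean",
            "pct_diff_g2_vs_g1",
            "pct_diff_s910_vs_s12_group1",
            "pct_diff_s910_vs_s12_group2",
        )
        if c in report.columns
    ]
    shown = report[display_cols].copy()
    return shown.to_string(float_format=lambda v: f"{v:.{decimals}g}")
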