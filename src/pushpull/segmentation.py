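"""Phase segmentation and the relative-moment time scale.

One traversal of the circuit passes eight waypoints in the fixed order
1-2-3-4-5-6-7-1.  Consecutive waypoint triples define six overlapping
phases (P1-2-3 ... P6-7-1), each with a begin, middle and end event.

The analysis window of a phase (its *sub-segment*) is the last 30% of
the first leg plus the first 70% of the second leg::

    t_a = t_middle - 0.3 * (t_middle - t_start)
    t_b = t_middle + 0.7 * (t_end   - t_middle)

Times inside the window map piecewise-linearly onto the relative-moment
scale [-1, 1]: -1 at the window start, 0 exactly at the middle waypoint,
+1 at the window end.  The two branches have different slopes because
the window is asymmetric around the middle; both anchors are on the
window, not on the full phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "PHASE_LABELS",
    "EXPECTED_POSITIONS",
    "Phase",
    "SubSegment",
    "build_phases",
    "make_subsegment",
    "relative_moment",
    "window_indices",
    "segment_events",
]

PHASE_LABELS = ("P1-2-3", "P2-3-4", "P3-4-5", "P4-5-6", "P5-6-7", "P6-7-1")
#: waypoint order of one traversal (the final event is the return to 1)
EXPECTED_POSITIONS = (1, 2, 3, 4, 5, 6, 7, 1)
EVENTS_PER_TRAVERSAL = len(EXPECTED_POSITIONS)


@dataclass(frozen=True)
class Phase:
    """A begin/middle/end waypoint triple of one traversal."""

    traversal_index: int
    label: str
    t_start: float
    t_middle: float
    t_end: float

    def __post_init__(self) -> None:
        if self.label not in PHASE_LABELS:
            raise ValidationError(f"unknown phase label {self.label!r}")
        if not self.t_start < self.t_middle < self.t_end:
            raise ValidationError(
                f"traversal {self.traversal_index} phase {self.label}: timestamps "
                f"must satisfy t_start < t_middle < t_end, got "
                f"({self.t_start}, {self.t_middle}, {self.t_end})"
            )


@dataclass(frozen=True)
class SubSegment:
    """The 30%/70% analysis window of a phase."""

    phase: Phase
    t_a: float
    t_b: float

    def __post_init__(self) -> None:
        p = self.phase
        if not (p.t_start <= self.t_a < p.t_middle < self.t_b <= p.t_end):
            raise ValidationError(
                f"sub-segment window ({self.t_a}, {self.t_b}) must bracket the "
                f"middle event and stay within phase ({p.t_start}, {p.t_end})"
            )


def build_phases(events: Iterable[tuple[int, float]] | pd.DataFrame,
                 traversal_index: int | None = None) -> list[Phase]:
    """Convert one traversal's eight position events into its six phases.

    ``events`` is an ordered sequence of ``(position, timestamp)`` pairs
    (or a DataFrame with ``position`` and ``time`` columns) that must
    follow the fixed waypoint order with strictly increasing timestamps.
    Consecutive phases share two events.
    """
    if isinstance(events, pd.DataFrame):
        if traversal_index is None and "traversal" in events.columns:
            trav = set(events["traversal"].tolist())
            if len(trav) != 1:
                raise ValidationError(
                    f"expected events of a single traversal, got traversals {sorted(trav)}"
                )
            traversal_index = int(next(iter(trav)))
        pairs = list(zip(events["position"].tolist(), events["time"].tolist()))
    else:
        pairs = list(events)
    trav = traversal_index if traversal_index is not None else 0
    if len(pairs) != EVENTS_PER_TRAVERSAL:
        raise ValidationError(
            f"traversal {trav}: expected {EVENTS_PER_TRAVERSAL} position events, "
            f"got {len(pairs)}"
        )
    positions = tuple(int(p) for p, _ in pairs)
    if positions != EXPECTED_POSITIONS:
        raise ValidationError(
            f"traversal {trav}: position order {positions} does not match the "
            f"required circuit {EXPECTED_POSITIONS}"
        )
    times = [float(t) for _, t in pairs]
    if not all(a < b for a, b in zip(times, times[1:])):
        raise ValidationError(
            f"traversal {trav}: event timestamps must be strictly increasing, got {times}"
        )
    return [
        Phase(trav, PHASE_LABELS[i], times[i], times[i + 1], times[i + 2])
        for i in range(6)
    ]


def make_subsegment(phase: Phase) -> SubSegment:
    """Derive a phase's 30%/70% analysis window."""
    t_a = phase.t_middle - 0.3 * (phase.t_middle - phase.t_start)
    t_b = phase.t_middle + 0.7 * (phase.t_end - phase.t_middle)
    return SubSegment(phase=phase, t_a=t_a, t_b=t_b)


def _as_subsegment(phase_or_sub: Phase | SubSegment) -> SubSegment:
    if isinstance(phase_or_sub, SubSegment):
        return phase_or_sub
    return make_subsegment(phase_or_sub)


def relative_moment(t, phase_or_sub: Phase | SubSegment):
    """Map time(s) inside the analysis window onto the [-1, 1] scale.

    Piecewise linear with 0 exactly at the middle event, -1 at the
    window start and +1 at the window end; strictly increasing and
    continuous at the middle.  Raises for times outside the window.
    Accepts a scalar or an array; given a :class:`Phase`, the default
    sub-segment window is used.
    """
    sub = _as_subsegment(phase_or_sub)
    tm = sub.phase.t_middle
    left = tm - sub.t_a
    right = sub.t_b - tm
    t_arr = np.asarray(t, dtype=float)
    tol = 1e-9 * max(1.0, sub.t_b - sub.t_a)
    if np.any(t_arr < sub.t_a - tol) or np.any(t_arr > sub.t_b + tol):
        raise ValidationError(
            f"time outside the analysis window [{sub.t_a}, {sub.t_b}]"
        )
    out = np.where(t_arr <= tm, (t_arr - tm) / left, (t_arr - tm) / right)
    out = np.clip(out, -1.0, 1.0)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def window_indices(
    sub: SubSegment, sample_rate: float, t0: float = 0.0, n_samples: int | None = None
) -> tuple[int, int]:
    """Inclusive sample-index bounds of a window on a uniform time grid.

    Sample ``i`` sits at ``t0 + i / sample_rate``; the window maps to
    ``[ceil(t_a * fs), floor(t_b * fs)]`` (relative to ``t0``), which
    makes windows reproducible across implementations.
    """
    eps = 1e-6
    i0 = int(np.ceil((sub.t_a - t0) * sample_rate - eps))
    i1 = int(np.floor((sub.t_b - t0) * sample_rate + eps))
    if i0 < 0 or (n_samples is not None and i1 >= n_samples):
        raise ValidationError(
            f"analysis window [{sub.t_a}, {sub.t_b}] s falls outside the recording"
        )
    if i1 < i0:
        raise ValidationError(
            f"analysis window [{sub.t_a}, {sub.t_b}] s contains no samples at "
            f"{sample_rate} Hz"
        )
    return i0, i1


def segment_events(events: pd.DataFrame) -> pd.DataFrame:
    """Segment a whole session's event stream into phases + windows.

    ``events`` must have columns ``traversal``, ``position``, ``time``.
    Returns one row per (traversal, phase) with the event timestamps and
    the window bounds ``t_a``/``t_b``.
    """
    required = {"traversal", "position", "time"}
    missing = required - set(events.columns)
    if missing:
        raise ValidationError(f"events table is missing columns: {sorted(missing)}")
    rows = []
    for trav, grp in events.groupby("traversal", sort=True):
        phases = build_phases(grp, traversal_index=int(trav))
        for ph in phases:
            sub = make_subsegment(ph)
            rows.append(
                {
                    "traversal": ph.traversal_index,
                    "phase": ph.label,
                    "t_start": ph.t_start,
                    "t_middle": ph.t_middle,
                    "t_end": ph.t_end,
                    "t_a": sub.t_a,
                    "t_b": sub.t_b,
                }
            )
    return pd.DataFrame(rows)
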