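"""Per-sub-segment force, time and EMG features.

For each analysis window and handle side the resultant-force series
yields: mean, standard deviation, max, min, the time integral (area
under the curve, an impulse-like quantity in force units x seconds),
the relative moments of the max and min, the maximal difference of
consecutive extrema, and the counts of local maxima and minima.  Local
extrema are counted with a prominence floor (a fraction of the window's
range) and a minimal separation, because unsmoothed 100 Hz force data
would otherwise make the counts noise-dominated.

Per phase there are three time-domain features: overall duration,
position-related task time (begin to middle), and the relative moment
of the middle event (0 by construction under the default window
mapping; emitted for table fidelity).

Per window and EMG channel the single feature is the mean absolute
value (MAV) of the MVC-normalized envelope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .exceptions import ValidationError
from .segmentation import Phase, SubSegment, relative_moment, window_indices
from .signals import mav

__all__ = [
    "PeakParams",
    "Extremum",
    "ForceSideFeatures",
    "TimeFeatures",
    "EMG_CHANNELS",
    "find_local_extrema",
    "extract_force_features",
    "extract_time_features",
    "extract_emg_features",
]

EMG_CHANNELS = (
    "back_left",
    "back_right",
    "chest_left",
    "chest_right",
    "arm_left",
    "arm_right",
)


@dataclass(frozen=True)
class PeakParams:
    """Criteria for a local extremum to count.

    ``prominence_fraction`` is the required prominence as a fraction of
    the window's max-min range; ``min_separation`` is the minimal
    spacing between counted extrema of the same kind, in seconds.
    """

    prominence_fraction: float = 0.05
    min_separation: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.prominence_fraction <= 1.0:
            raise ValidationError(
                f"prominence_fraction must be in [0, 1], got {self.prominence_fraction}"
            )
        if self.min_separation < 0:
            raise ValidationError(f"min_separation must be >= 0, got {self.min_separation}")


@dataclass(frozen=True)
class Extremum:
    index: int
    kind: str  # "max" or "min"
    value: float


def _alternating(extrema: list[Extremum]) -> list[Extremum]:
    """Merge same-kind neighbours, keeping the more extreme one."""
    out: list[Extremum] = []
    for e in extrema:
        if out and out[-1].kind == e.kind:
            prev = out[-1]
            if (e.kind == "max" and e.value > prev.value) or (
                e.kind == "min" and e.value < prev.value
            ):
                out[-1] = e
        else:
            out.append(e)
    return out


def find_local_extrema(
    values: Sequence[float],
    sample_rate: float,
    params: PeakParams | None = None,
) -> list[Extremum]:
    """Prominence- and separation-filtered local extrema of a window.

    Maxima and minima are detected independently (minima on the negated
    series), each requiring prominence >= ``prominence_fraction`` times
    the window range; when several candidates fall within
    ``min_separation`` the taller (deeper) one wins.  The merged
    sequence strictly alternates max/min: same-kind neighbours are
    collapsed to the more extreme one, so the two counts differ by at
    most 1.
    """
    params = params or PeakParams()
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValidationError(f"window has {x.size} samples; need >= 3 to find extrema")
    rng = float(np.max(x) - np.min(x))
    if rng == 0.0:
        return []
    prominence = params.prominence_fraction * rng
    distance = max(1.0, params.min_separation * sample_rate)
    kw = {"distance": distance}
    if prominence > 0:
        kw["prominence"] = prominence
    imax, _ = find_peaks(x, **kw)
    imin, _ = find_peaks(-x, **kw)
    merged = sorted(
        [Extremum(int(i), "max", float(x[i])) for i in imax]
        + [Extremum(int(i), "min", float(x[i])) for i in imin],
        key=lambda e: e.index,
    )
    return _alternating(merged)


@dataclass(frozen=True)
class ForceSideFeatures:
    """The ten per-side force parameters of one analysis window."""

    mean: float
    sd: float
    max: float
    min: float
    integral: float  # force units * seconds
    rel_moment_max: float
    rel_moment_min: float
    max_consecutive_extremum_diff: float
    n_local_maxima: int
    n_local_minima: int

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean,
            "std": self.sd,
            "max": self.max,
            "min": self.min,
            "integral": self.integral,
            "rel_moment_max": self.rel_moment_max,
            "rel_moment_min": self.rel_moment_min,
            "max_consec_extremum_diff": self.max_consecutive_extremum_diff,
            "n_local_maxima": float(self.n_local_maxima),
            "n_local_minima": float(self.n_local_minima),
        }


def extract_force_features(
    force: Sequence[float],
    sub: SubSegment,
    sample_rate: float,
    params: PeakParams | None = None,
    t0: float = 0.0,
) -> ForceSideFeatures:
    """Compute the per-side force feature set on one analysis window.

    ``force`` is the full-session resultant-magnitude series on the
    uniform grid ``t0 + i / sample_rate``; the window samples are
    selected by the reproducible ceil/floor index rule.  The integral
    uses the trapezoidal rule (exact for piecewise-linear signals
    sampled at their breakpoints); argmax/argmin ties resolve to the
    first occurrence.
    """
    force = np.asarray(force, dtype=float)
    i0, i1 = window_indices(sub, sample_rate, t0=t0, n_samples=force.size)
    w = force[i0 : i1 + 1]
    if w.size < 3:
        raise ValidationError(
            f"analysis window [{sub.t_a}, {sub.t_b}] s holds only {w.size} samples"
        )
    times = t0 + np.arange(i0, i1 + 1) / sample_rate
    extrema = find_local_extrema(w, sample_rate, params)
    max_diff = 0.0
    if len(extrema) >= 2:
        vals = np.array([e.value for e in extrema])
        max_diff = float(np.max(np.abs(np.diff(vals))))
    n_max = sum(1 for e in extrema if e.kind == "max")
    n_min = sum(1 for e in extrema if e.kind == "min")
    return ForceSideFeatures(
        mean=float(np.mean(w)),
        sd=float(np.std(w, ddof=1)),
        max=float(np.max(w)),
        min=float(np.min(w)),
        integral=float(np.trapezoid(w, dx=1.0 / sample_rate)),
        rel_moment_max=float(relative_moment(times[int(np.argmax(w))], sub)),
        rel_moment_min=float(relative_moment(times[int(np.argmin(w))], sub)),
        max_consecutive_extremum_diff=max_diff,
        n_local_maxima=n_max,
        n_local_minima=n_min,
    )


@dataclass(frozen=True)
class TimeFeatures:
    """Per-phase timing parameters."""

    overall_duration: float  # t_end - t_start, seconds
    position_related_task_time: float  # t_middle - t_start, seconds
    rel_moment_middle: float  # 0 under the default window mapping


def extract_time_features(phase: Phase) -> TimeFeatures:
    return TimeFeatures(
        overall_duration=phase.t_end - phase.t_start,
        position_related_task_time=phase.t_middle - phase.t_start,
        rel_moment_middle=0.0,
    )


def extract_emg_features(
    norm_emg: Mapping[str, Sequence[float]],
    sub: SubSegment,
    sample_rate: float,
    t0: float = 0.0,
    channels: Sequence[str] = EMG_CHANNELS,
) -> dict[str, float]:
    """Per-channel MAV of the MVC-normalized envelopes on one window."""
    out: dict[str, float] = {}
    for ch in channels:
        if ch not in norm_emg:
            raise ValidationError(f"missing EMG channel {ch!r}")
        series = np.asarray(norm_emg[ch], dtype=float)
        i0, i1 = window_indices(sub, sample_rate, t0=t0, n_samples=series.size)
        out[ch] = mav(series[i0 : i1 + 1])
    return out
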