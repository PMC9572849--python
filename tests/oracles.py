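"""Independent brute-force oracles used to cross-check the fast paths.

The extrema oracle works directly from the definitions: 3-point
comparison for candidates, prominence by explicitly walking out to the
nearest strictly-higher sample on each side and taking the bases'
maximum, minimal separation by keeping peaks tallest-first, and the
same alternation contract (same-kind neighbours collapse to the more
extreme one).  It is O(n^2) and shares no code with the package's
implementation.
"""

from __future__ import annotations

import math

import numpy as np


def _three_point_maxima(y: np.ndarray) -> list[int]:
    return [i for i in range(1, y.size - 1) if y[i - 1] < y[i] and y[i] > y[i + 1]]


def _prominence(y: np.ndarray, i: int) -> float:
    left_min = y[i]
    j = i - 1
    while j >= 0 and y[j] <= y[i]:
        left_min = min(left_min, y[j])
        j -= 1
    right_min = y[i]
    k = i + 1
    while k < y.size and y[k] <= y[i]:
        right_min = min(right_min, y[k])
        k += 1
    return y[i] - max(left_min, right_min)


def _keep_tallest_first(idx: list[int], y: np.ndarray, distance: float) -> list[int]:
    dist = math.ceil(distance)
    removed = {j: False for j in idx}
    for j in sorted(idx, key=lambda i: y[i], reverse=True):
        if removed[j]:
            continue
        for k in idx:
            if k != j and not removed[k] and abs(k - j) < dist:
                removed[k] = True
    return sorted(j for j in idx if not removed[j])


def _one_kind(y: np.ndarray, prominence: float, distance: float) -> list[int]:
    idx = _three_point_maxima(y)
    idx = _keep_tallest_first(idx, y, distance)
    if prominence > 0:
        idx = [i for i in idx if _prominence(y, i) >= prominence]
    return idx


def brute_force_extrema(
    values,
    sample_rate: float,
    prominence_fraction: float = 0.05,
    min_separation: float = 0.1,
) -> list[tuple[int, str, float]]:
    """Reference extrema finder; returns the alternating (index, kind, value) list."""
    x = np.asarray(values, dtype=float)
    rng = x.max() - x.min()
    if rng == 0:
        return []
    prominence = prominence_fraction * rng
    distance = max(1.0, min_separation * sample_rate)
    events = sorted(
        [(i, "max", float(x[i])) for i in _one_kind(x, prominence, distance)]
        + [(i, "min", float(x[i])) for i in _one_kind(-x, prominence, distance)]
    )
    out: list[tuple[int, str, float]] = []
    for ev in events:
        if out and out[-1][1] == ev[1]:
            prev = out[-1]
            better = (ev[1] == "max" and ev[2] > prev[2]) or (
                ev[1] == "min" and ev[2] < prev[2]
            )
            if better:
                out[-1] = ev
        else:
            out.append(ev)
    return out
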