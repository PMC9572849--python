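"""Psychometric scoring and cohort classification.

Participants are characterised by three DASS scale totals (depression,
anxiety, stress; 14 items each, 0-3 per item, totals 0-42), a Starkstein
apathy total (0-42), and three clinical findings from a physical
examination: a straight-leg-raise flag, a reduced thoracolumbar
range-of-motion flag, and the number of active (painful) trigger points
of the upper limb (VRS 3-4 on palpation, out of 10 investigated points).

Two extreme groups are formed from these assessments:

* ``GROUP1`` -- no psychometric total at or above its clinical threshold,
  no active trigger points, normal spinal mobility;
* ``GROUP2`` -- at least two totals at/above threshold, at least two
  active trigger points, and reduced spinal mobility.

Everything else is ``UNCLASSIFIED``.  Thresholds default to the mapping
consistent with the study cohort table (stress >= 15, anxiety >= 8,
depression >= 10, apathy >= 14; all inclusive) and are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "DASS_SCALES",
    "DassItemResponses",
    "ParticipantRecord",
    "PsychThresholds",
    "PsychFlags",
    "GroupLabel",
    "CohortSummary",
    "score_dass",
    "flag_psych",
    "assign_group",
    "label_cohort",
    "summarize_cohort",
    "trigger_point_count_from_vrs",
]

DASS_SCALES = ("stress", "anxiety", "depression")
DASS_ITEMS_PER_SCALE = 14
DASS_ITEM_MAX = 3
SCORE_MAX = 42


def _check_items(scale: str, items: Sequence[int]) -> tuple[int, ...]:
    items = tuple(items)
    if len(items) != DASS_ITEMS_PER_SCALE:
        raise ValidationError(
            f"DASS scale '{scale}' needs exactly {DASS_ITEMS_PER_SCALE} item "
            f"responses, got {len(items)}"
        )
    for i, v in enumerate(items, start=1):
        if not (isinstance(v, (int, np.integer)) and 0 <= v <= DASS_ITEM_MAX):
            raise ValidationError(
                f"DASS scale '{scale}' item {i}: response {v!r} is not an "
                f"integer in 0..{DASS_ITEM_MAX}"
            )
    return items


@dataclass(frozen=True)
class DassItemResponses:
    """Raw per-item DASS responses, 14 items per scale, each in 0-3."""

    stress: tuple[int, ...]
    anxiety: tuple[int, ...]
    depression: tuple[int, ...]

    def __post_init__(self) -> None:
        for scale in DASS_SCALES:
            object.__setattr__(self, scale, _check_items(scale, getattr(self, scale)))


def score_dass(responses: DassItemResponses) -> tuple[int, int, int]:
    """Sum the item responses of each scale.

    Returns ``(stress_total, anxiety_total, depression_total)``, each in
    0-42.
    """
    return (
        int(sum(responses.stress)),
        int(sum(responses.anxiety)),
        int(sum(responses.depression)),
    )


@dataclass(frozen=True)
class PsychThresholds:
    """Inclusive clinical cut-offs for the four psychometric totals."""

    stress: int = 15
    anxiety: int = 8
    depression: int = 10
    apathy: int = 14

    def __post_init__(self) -> None:
        for name in ("stress", "anxiety", "depression", "apathy"):
            v = getattr(self, name)
            if not 0 <= v <= SCORE_MAX:
                raise ValidationError(
                    f"threshold '{name}' must be in 0..{SCORE_MAX}, got {v}"
                )


@dataclass(frozen=True)
class ParticipantRecord:
    """One row of the participant characteristics table."""

    participant_id: int
    age: float  # years
    weight: float  # kg
    height: float  # cm
    dass_stress_total: int
    dass_anxiety_total: int
    dass_depression_total: int
    apathy_total: int
    straight_leg_raise_positive: bool
    reduced_rom: bool  # reduced range of motion of the thoracolumbar spine
    trigger_point_count: int  # active (VRS 3-4) trigger points, 0-10

    def __post_init__(self) -> None:
        if self.participant_id <= 0:
            raise ValidationError(f"participant_id must be positive, got {self.participant_id}")
        for name in ("age", "weight", "height"):
            if not getattr(self, name) > 0:
                raise ValidationError(
                    f"participant {self.participant_id}: {name} must be strictly "
                    f"positive, got {getattr(self, name)}"
                )
        for name in (
            "dass_stress_total",
            "dass_anxiety_total",
            "dass_depression_total",
            "apathy_total",
        ):
            v = getattr(self, name)
            if not 0 <= v <= SCORE_MAX:
                raise ValidationError(
                    f"participant {self.participant_id}: {name} must be in "
                    f"0..{SCORE_MAX}, got {v}"
                )
        if not 0 <= self.trigger_point_count <= 10:
            raise ValidationError(
                f"participant {self.participant_id}: trigger_point_count must be "
                f"in 0..10, got {self.trigger_point_count}"
            )


@dataclass(frozen=True)
class PsychFlags:
    """Threshold exceedance flags for one participant."""

    stress_high: bool
    anxiety_high: bool
    depression_high: bool
    apathy_high: bool

    @property
    def n_high(self) -> int:
        return sum(
            (self.stress_high, self.anxiety_high, self.depression_high, self.apathy_high)
        )


class GroupLabel(str, Enum):
    GROUP1 = "GROUP1"
    GROUP2 = "GROUP2"
    UNCLASSIFIED = "UNCLASSIFIED"


def flag_psych(
    record: ParticipantRecord, thresholds: PsychThresholds | None = None
) -> PsychFlags:
    """Flag each psychometric total at or above its threshold (inclusive)."""
    thr = thresholds or PsychThresholds()
    return PsychFlags(
        stress_high=record.dass_stress_total >= thr.stress,
        anxiety_high=record.dass_anxiety_total >= thr.anxiety,
        depression_high=record.dass_depression_total >= thr.depression,
        apathy_high=record.apathy_total >= thr.apathy,
    )


def assign_group(
    record: ParticipantRecord, flags: PsychFlags | None = None,
    thresholds: PsychThresholds | None = None,
) -> GroupLabel:
    """Assign a participant to GROUP1 / GROUP2 / UNCLASSIFIED.

    GROUP1: no high psychometric score, zero active trigger points and
    normal thoracolumbar mobility.  GROUP2: at least two high scores, at
    least two active trigger points and reduced mobility.  The criteria
    are mutually exclusive by construction (0 vs >= 2 high scores).
    """
    if flags is None:
        flags = flag_psych(record, thresholds)
    if flags.n_high == 0 and record.trigger_point_count == 0 and not record.reduced_rom:
        return GroupLabel.GROUP1
    if flags.n_high >= 2 and record.trigger_point_count >= 2 and record.reduced_rom:
        return GroupLabel.GROUP2
    return GroupLabel.UNCLASSIFIED


def label_cohort(
    records: Iterable[ParticipantRecord], thresholds: PsychThresholds | None = None
) -> dict[int, GroupLabel]:
    """Group label per participant id."""
    return {r.participant_id: assign_group(r, thresholds=thresholds) for r in records}


def trigger_point_count_from_vrs(scores: Iterable[int]) -> int:
    """Count active trigger points from raw per-point VRS pain scores (0-4).

    A point is active when scored 3 ('severe pain') or 4 ('very severe
    pain').
    """
    scores = list(scores)
    if len(scores) > 10:
        raise ValidationError(f"at most 10 trigger points are scored, got {len(scores)}")
    for i, s in enumerate(scores, start=1):
        if not (isinstance(s, (int, np.integer)) and 0 <= s <= 4):
            raise ValidationError(f"VRS score at point {i} must be an integer in 0..4, got {s!r}")
    return sum(1 for s in scores if s >= 3)


@dataclass(frozen=True)
class CohortSummary:
    n: int
    age_mean: float
    age_sd: float
    weight_mean: float
    weight_sd: float
    height_mean: float
    height_sd: float
    n_group1: int
    n_group2: int
    n_unclassified: int


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    if values.size == 1:
        warnings.warn(
            "standard deviation undefined for a single record; reporting 0",
            stacklevel=3,
        )
        return float(values[0]), 0.0
    return float(np.mean(values)), float(np.std(values, ddof=1))


def summarize_cohort(
    records: Sequence[ParticipantRecord], thresholds: PsychThresholds | None = None
) -> CohortSummary:
    """Anthropometric means/SDs (n-1 denominator) and group sizes."""
    if len(records) == 0:
        raise ValidationError("cannot summarize an empty cohort")
    labels = [assign_group(r, thresholds=thresholds) for r in records]
    age_m, age_s = _mean_sd(np.array([r.age for r in records], dtype=float))
    w_m, w_s = _mean_sd(np.array([r.weight for r in records], dtype=float))
    h_m, h_s = _mean_sd(np.array([r.height for r in records], dtype=float))
    return CohortSummary(
        n=len(records),
        age_mean=age_m,
        age_sd=age_s,
        weight_mean=w_m,
        weight_sd=w_s,
        height_mean=h_m,
        height_sd=h_s,
        n_group1=labels.count(GroupLabel.GROUP1),
        n_group2=labels.count(GroupLabel.GROUP2),
        n_unclassified=labels.count(GroupLabel.UNCLASSIFIED),
    )
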