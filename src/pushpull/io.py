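"""CSV readers/writers and run manifests.

All artifacts are plain CSV (UTF-8, '.' decimal separator, header row);
processed outputs carry a ``# key: value`` metadata header block naming
the parameter values that produced them.  Write-then-read round-trips
preserve values to full float precision.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import DASS_SCALES, DassItemResponses, GroupLabel, ParticipantRecord
from .exceptions import ValidationError
from .features import EMG_CHANNELS
from .simulate import FORCE_CHANNELS, MVCTrialSet, SessionRecording

__all__ = [
    "read_participants",
    "write_participants",
    "read_session",
    "write_session",
    "read_mvc_trials",
    "write_mvc_trials",
    "read_events",
    "write_features",
    "read_features",
    "write_labels",
    "read_labels",
    "write_manifest",
]

EMG_COLUMNS = tuple(f"emg_{ch}" for ch in EMG_CHANNELS)
SIGNAL_COLUMNS = ("time",) + FORCE_CHANNELS + EMG_COLUMNS
EVENT_COLUMNS = ("traversal", "event_index", "position", "time")

_PARTICIPANT_COLUMNS = (
    "participant_id",
    "age",
    "weight",
    "height",
    "dass_stress_total",
    "dass_anxiety_total",
    "dass_depression_total",
    "apathy_total",
    "straight_leg_raise_positive",
    "reduced_rom",
    "trigger_point_count",
)


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = set(required) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")


def read_participants(path) -> list[ParticipantRecord]:
    """Read a participant table; malformed rows are rejected with line numbers."""
    df = pd.read_csv(path)
    _require_columns(df, _PARTICIPANT_COLUMNS, path)
    records = []
    seen: dict[int, int] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            rec = ParticipantRecord(
                participant_id=int(row.participant_id),
                age=float(row.age),
                weight=float(row.weight),
                height=float(row.height),
                dass_stress_total=int(row.dass_stress_total),
                dass_anxiety_total=int(row.dass_anxiety_total),
                dass_depression_total=int(row.dass_depression_total),
                apathy_total=int(row.apathy_total),
                straight_leg_raise_positive=bool(int(row.straight_leg_raise_positive)),
                reduced_rom=bool(int(row.reduced_rom)),
                trigger_point_count=int(row.trigger_point_count),
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}, line {line}: {exc}") from None
        if rec.participant_id in seen:
            raise ValidationError(
                f"{path}, line {line}: duplicate participant id "
                f"{rec.participant_id} (first seen on line {seen[rec.participant_id]})"
            )
        seen[rec.participant_id] = line
        records.append(rec)
    return records


def write_participants(records, path) -> None:
    df = pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "age": r.age,
                "weight": r.weight,
                "height": r.height,
                "dass_stress_total": r.dass_stress_total,
                "dass_anxiety_total": r.dass_anxiety_total,
                "dass_depression_total": r.dass_depression_total,
                "apathy_total": r.apathy_total,
                "straight_leg_raise_positive": int(r.straight_leg_raise_positive),
                "reduced_rom": int(r.reduced_rom),
                "trigger_point_count": r.trigger_point_count,
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)


def read_dass_items(path) -> dict[int, DassItemResponses]:
    """Read raw per-item DASS responses.

    Expected columns: ``participant_id``, ``scale`` (stress / anxiety /
    depression), ``item_index`` (1-14), ``response`` (0-3); exactly 14
    items per scale per participant.
    """
    df = pd.read_csv(path)
    _require_columns(df, ("participant_id", "scale", "item_index", "response"), path)
    out: dict[int, DassItemResponses] = {}
    for pid, grp in df.groupby("participant_id"):
        scales = {}
        for scale in DASS_SCALES:
            sub = grp[grp["scale"] == scale].sort_values("item_index")
            if list(sub["item_index"]) != list(range(1, 15)):
                raise ValidationError(
                    f"{path}: participant {pid}, scale '{scale}': item indices "
                    f"must be exactly 1..14"
                )
            scales[scale] = tuple(int(v) for v in sub["response"])
        out[int(pid)] = DassItemResponses(**scales)
    return out


def read_events(path) -> pd.DataFrame:
    """Read a position-event stream, checking the timestamp grammar."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, EVENT_COLUMNS, path)
    for trav, grp in df.groupby("traversal"):
        t = grp["time"].to_numpy()
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            line = int(grp.index[bad[0] + 1]) + 2
            raise ValidationError(
                f"{path}, line {line}: event timestamps of traversal {trav} are "
                f"not strictly increasing"
            )
    return df


def write_session(recording: SessionRecording, signals_path, events_path) -> None:
    """Write one session as a signals CSV + events CSV pair."""
    data = {"time": recording.time}
    for ch in FORCE_CHANNELS:
        data[ch] = recording.force[ch]
    for ch in EMG_CHANNELS:
        data[f"emg_{ch}"] = recording.emg[ch]
    pd.DataFrame(data).to_csv(signals_path, index=False)
    recording.events.to_csv(events_path, index=False)


def read_session(signals_path, events_path) -> SessionRecording:
    """Read a signals/events CSV pair back into a recording."""
    df = pd.read_csv(signals_path, float_precision="round_trip")
    _require_columns(df, SIGNAL_COLUMNS, signals_path)
    t = df["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValidationError(f"{signals_path}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        line = int(np.nonzero(dt <= 0)[0][0]) + 3
        raise ValidationError(f"{signals_path}, line {line}: time axis is not increasing")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValidationError(f"{signals_path}: time axis is not uniformly sampled")
    events = read_events(events_path)
    return SessionRecording(
        time=t,
        sample_rate=1.0 / float(np.mean(dt)),
        force={ch: df[ch].to_numpy(dtype=float) for ch in FORCE_CHANNELS},
        emg={ch: df[f"emg_{ch}"].to_numpy(dtype=float) for ch in EMG_CHANNELS},
        events=events,
        meta={"source": str(signals_path)},
    )


def write_mvc_trials(trials: MVCTrialSet, path) -> None:
    data = {"time": trials.time}
    for ch in EMG_CHANNELS:
        data[ch] = trials.trials[ch]
    pd.DataFrame(data).to_csv(path, index=False)


def read_mvc_trials(path) -> MVCTrialSet:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("time",) + EMG_CHANNELS, path)
    t = df["time"].to_numpy(dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValidationError(f"{path}: MVC trial time axis must be increasing")
    return MVCTrialSet(
        time=t,
        sample_rate=1.0 / float(np.mean(np.diff(t))),
        trials={ch: df[ch].to_numpy(dtype=float) for ch in EMG_CHANNELS},
    )


def write_features(features: pd.DataFrame, path, metadata: Mapping | None = None) -> None:
    """Write the long-format features table with a metadata header block."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        features.to_csv(fh, index=False)


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    _require_columns(df, ("participant", "traversal", "phase", "parameter", "value"), path)
    return df


def write_labels(labels: Mapping[int, GroupLabel], path) -> None:
    pd.DataFrame(
        {"participant": list(labels), "group": [GroupLabel(v).value for v in labels.values()]}
    ).to_csv(path, index=False)


def read_labels(path) -> dict[int, GroupLabel]:
    df = pd.read_csv(path)
    _require_columns(df, ("participant", "group"), path)
    try:
        return {int(p): GroupLabel(g) for p, g in zip(df["participant"], df["group"])}
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_manifest(manifest: Mapping, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(manifest), fh, sort_keys=True)


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
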