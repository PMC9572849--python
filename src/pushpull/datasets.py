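"""Bundled reference data.

``load_participants`` ships the 20-man participant characteristics
table of the motivating handcart study (anthropometrics, DASS totals,
apathy total, clinical flags).  ``load_reference_group_means`` ships
the published group-mean force and EMG parameter tables together with
their printed percent-difference columns; the means serve as worked-
example inputs for the contrast machinery (the underlying raw
recordings were never deposited, so they cannot be recomputed).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohort import ParticipantRecord
from .exceptions import ValidationError

__all__ = [
    "load_participants",
    "participants_dataframe",
    "load_reference_group_means",
    "participants_path",
]


def _data_path(name: str):
    return resources.files("pushpull.data").joinpath(name)


def participants_path() -> str:
    """Filesystem path of the bundled participant table CSV."""
    return str(_data_path("participants.csv"))


def participants_dataframe() -> pd.DataFrame:
    return pd.read_csv(_data_path("participants.csv"))


def load_participants() -> list[ParticipantRecord]:
    """The bundled participant table as validated records."""
    df = participants_dataframe()
    return [
        ParticipantRecord(
            participant_id=int(r.participant_id),
            age=float(r.age),
            weight=float(r.weight),
            height=float(r.height),
            dass_stress_total=int(r.dass_stress_total),
            dass_anxiety_total=int(r.dass_anxiety_total),
            dass_depression_total=int(r.dass_depression_total),
            apathy_total=int(r.apathy_total),
            straight_leg_raise_positive=bool(r.straight_leg_raise_positive),
            reduced_rom=bool(r.reduced_rom),
            trigger_point_count=int(r.trigger_point_count),
        )
        for r in df.itertuples(index=False)
    ]


def load_reference_group_means(kind: str = "force") -> pd.DataFrame:
    """Published group-mean parameter tables (``kind``: 'force' or 'emg').

    Indexed by display parameter name, with columns ``group1_mean``,
    ``group2_mean`` and the three printed percent-difference columns.
    """
    if kind not in ("force", "emg"):
        raise ValidationError(f"kind must be 'force' or 'emg', got {kind!r}")
    df = pd.read_csv(_data_path(f"reference_{kind}_means.csv"))
    return df.set_index("parameter")
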