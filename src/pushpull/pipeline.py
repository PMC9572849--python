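"""End-to-end orchestration: score -> preprocess -> segment -> extract -> compare.

``run_pipeline`` drives the whole analysis from a single config, either
on a simulated two-group cohort or on per-participant CSV files, and
writes the features table, the group labels, the comparison report
(CSV + aligned text) and a run manifest carrying every parameter value
and the seed.  Given the same config and seed the machine-readable
outputs are byte-identical.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .cohort import GroupLabel, PsychThresholds, label_cohort
from .compare import aggregate_group, build_report, render_report, series_contrast
from .exceptions import ValidationError
from .features import (
    EMG_CHANNELS,
    PeakParams,
    extract_emg_features,
    extract_force_features,
    extract_time_features,
)
from .io import (
    ensure_dir,
    read_mvc_trials,
    read_participants,
    read_session,
    write_features,
    write_labels,
    write_manifest,
    write_participants,
)
from .segmentation import SubSegment, build_phases, make_subsegment
from .signals import EmgPreprocessParams, extract_mvc, force_magnitude, normalize_emg, preprocess_emg
from .simulate import (
    MVCTrialSet,
    SessionRecording,
    group1_reference_config,
    group2_reference_config,
    simulate_cohort,
)

__all__ = [
    "PipelineConfig",
    "SessionInput",
    "PipelineResult",
    "mvc_from_trials",
    "normalized_emg_channels",
    "session_feature_table",
    "analyze_participant",
    "run_pipeline",
    "load_config",
]

logger = logging.getLogger("pushpull")


@dataclass(frozen=True)
class SessionInput:
    """Paths of one participant's recorded data."""

    participant_id: int
    signals: str
    events: str
    mvc: str


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str = "pushpull_out"
    seed: int = 0
    thresholds: PsychThresholds = field(default_factory=PsychThresholds)
    emg_params: EmgPreprocessParams = field(default_factory=EmgPreprocessParams)
    peak_params: PeakParams = field(default_factory=PeakParams)
    window_mode: str = "subsegment"  # or "phase" (sensitivity analysis)
    # simulate mode
    simulate: bool = True
    n_group1: int = 2
    n_group2: int = 3
    group1_overrides: dict = field(default_factory=dict)
    group2_overrides: dict = field(default_factory=dict)
    # file mode
    participants_path: str | None = None
    sessions: tuple[SessionInput, ...] = ()

    def __post_init__(self) -> None:
        if self.window_mode not in ("subsegment", "phase"):
            raise ValidationError(
                f"window_mode must be 'subsegment' or 'phase', got {self.window_mode!r}"
            )
        if not self.simulate and (self.participants_path is None or not self.sessions):
            raise ValidationError(
                "file mode needs participants_path and at least one session entry"
            )


@dataclass
class PipelineResult:
    out_dir: str
    labels: dict[int, GroupLabel]
    features: pd.DataFrame
    report: pd.DataFrame
    paths: dict[str, str]


def mvc_from_trials(
    trials: MVCTrialSet, params: EmgPreprocessParams | None = None
) -> dict[str, float]:
    """Per-channel MVC: maximum of the processed trial envelope."""
    params = params or EmgPreprocessParams()
    out = {}
    for ch in EMG_CHANNELS:
        env = preprocess_emg(trials.trials[ch], trials.sample_rate, params)
        out[ch] = extract_mvc(env, trials.sample_rate, params.envelope_window)
    return out


def normalized_emg_channels(
    recording: SessionRecording,
    mvc_values: Mapping[str, float],
    params: EmgPreprocessParams | None = None,
) -> dict[str, "pd.Series | object"]:
    """Preprocess and MVC-normalize all six EMG channels of a session."""
    params = params or EmgPreprocessParams()
    return {
        ch: normalize_emg(
            preprocess_emg(recording.emg[ch], recording.sample_rate, params),
            mvc_values[ch],
        )
        for ch in EMG_CHANNELS
    }


def _analysis_window(phase, mode: str) -> SubSegment:
    if mode == "phase":
        return SubSegment(phase=phase, t_a=phase.t_start, t_b=phase.t_end)
    return make_subsegment(phase)


def session_feature_table(
    recording: SessionRecording,
    norm_emg: Mapping[str, object],
    peak_params: PeakParams | None = None,
    window_mode: str = "subsegment",
) -> pd.DataFrame:
    """Long-format feature table of one session.

    One row per (traversal, phase, parameter): the ten force parameters
    per side, the three time parameters, and the six normalized-EMG
    MAVs, all computed on the phase's analysis window.
    """
    fs = recording.sample_rate
    t0 = float(recording.time[0])
    f_side = {
        "right": force_magnitude(
            recording.force["fxR"], recording.force["fyR"], recording.force["fzR"]
        ),
        "left": force_magnitude(
            recording.force["fxL"], recording.force["fyL"], recording.force["fzL"]
        ),
    }
    rows = []
    for trav, grp in recording.events.groupby("traversal", sort=True):
        for phase in build_phases(grp, traversal_index=int(trav)):
            sub = _analysis_window(phase, window_mode)
            for side in ("right", "left"):
                feats = extract_force_features(f_side[side], sub, fs, peak_params, t0=t0)
                for stat, value in feats.as_dict().items():
                    rows.append(
                        {
                            "traversal": int(trav),
                            "phase": phase.label,
                            "parameter": f"force_{stat}_{side}",
                            "value": value,
                        }
                    )
            tf = extract_time_features(phase)
            for name, value in (
                ("position_related_task_time", tf.position_related_task_time),
                ("overall_duration", tf.overall_duration),
                ("rel_moment_middle", tf.rel_moment_middle),
            ):
                rows.append(
                    {"traversal": int(trav), "phase": phase.label, "parameter": name, "value": value}
                )
            emg = extract_emg_features(norm_emg, sub, fs, t0=t0)
            for ch, value in emg.items():
                rows.append(
                    {
                        "traversal": int(trav),
                        "phase": phase.label,
                        "parameter": f"emg_mav_{ch}",
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


def analyze_participant(
    recording: SessionRecording,
    mvc_trials: MVCTrialSet,
    emg_params: EmgPreprocessParams | None = None,
    peak_params: PeakParams | None = None,
    window_mode: str = "subsegment",
) -> pd.DataFrame:
    """Full single-session analysis: MVC extraction through features."""
    mvc = mvc_from_trials(mvc_trials, emg_params)
    norm = normalized_emg_channels(recording, mvc, emg_params)
    return session_feature_table(recording, norm, peak_params, window_mode)


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = _time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = _time.perf_counter() - self.t0
            if exc_type is None:
                logger.info("stage %s: done in %.2f s", name, dt)
            else:
                logger.error("stage %s: failed after %.2f s", name, dt)
            return False

    return _Timer()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write the report bundle."""
    out = Path(ensure_dir(config.out_dir))
    paths = {
        "participants": str(out / "participants.csv"),
        "labels": str(out / "labels.csv"),
        "features": str(out / "features.csv"),
        "report_csv": str(out / "report.csv"),
        "report_txt": str(out / "report.txt"),
        "manifest": str(out / "manifest.yaml"),
    }

    try:
        with _stage("acquire"):
            if config.simulate:
                g1 = group1_reference_config(**config.group1_overrides)
                g2 = group2_reference_config(**config.group2_overrides)
                g1 = replace(g1, emg_params=config.emg_params)
                g2 = replace(g2, emg_params=config.emg_params)
                records, sessions = simulate_cohort(
                    config.n_group1, config.n_group2, g1, g2, seed=config.seed
                )
                write_participants(records, paths["participants"])
                inputs = {
                    pid: (sp.recording, sp.mvc_trials) for pid, sp in sessions.items()
                }
            else:
                records = read_participants(config.participants_path)
                inputs = {}
                for s in config.sessions:
                    inputs[s.participant_id] = (
                        read_session(s.signals, s.events),
                        read_mvc_trials(s.mvc),
                    )
                write_participants(records, paths["participants"])

        with _stage("score"):
            labels = label_cohort(records, config.thresholds)
            write_labels(labels, paths["labels"])
            logger.info(
                "group sizes: %s",
                {g.value: sum(1 for v in labels.values() if v == g) for g in GroupLabel},
            )

        with _stage("extract"):
            tables = []
            for pid in sorted(inputs):
                recording, trials = inputs[pid]
                table = analyze_participant(
                    recording,
                    trials,
                    config.emg_params,
                    config.peak_params,
                    config.window_mode,
                )
                table.insert(0, "participant", pid)
                tables.append(table)
            features = pd.concat(tables, ignore_index=True)
            write_features(
                features,
                paths["features"],
                metadata={
                    "pushpull_version": __version__,
                    "seed": config.seed,
                    "window_mode": config.window_mode,
                    "peak_prominence_fraction": config.peak_params.prominence_fraction,
                    "peak_min_separation_s": config.peak_params.min_separation,
                    "emg_bandpass_hz": f"{config.emg_params.bandpass_low}-{config.emg_params.bandpass_high}",
                    "emg_envelope_window_s": config.emg_params.envelope_window,
                    "emg_envelope_kind": config.emg_params.envelope_kind,
                },
            )

        with _stage("compare"):
            feat_labeled = {pid: labels[pid] for pid in inputs}
            aggregates = aggregate_group(features, feat_labeled)
            # full protocol: first-two vs last-two traversals (S1-2 vs S9-10);
            # shortened protocols fall back to first vs last
            travs = sorted(features["traversal"].unique())
            if len(travs) >= 4:
                early, late = tuple(travs[:2]), tuple(travs[-2:])
            else:
                early, late = (travs[0],), (travs[-1],)
            contrasts = series_contrast(features, feat_labeled, early=early, late=late)
            report = build_report(aggregates, contrasts)
            report.to_csv(paths["report_csv"])
            with open(paths["report_txt"], "w", encoding="utf-8") as fh:
                fh.write(render_report(report) + "\n")

        manifest = {
            "pushpull_version": __version__,
            "seed": config.seed,
            "window_mode": config.window_mode,
            "thresholds": vars(config.thresholds).copy(),
            "emg_params": vars(config.emg_params).copy(),
            "peak_params": vars(config.peak_params).copy(),
            "simulate": config.simulate,
            "n_group1": config.n_group1,
            "n_group2": config.n_group2,
            "group1_overrides": dict(config.group1_overrides),
            "group2_overrides": dict(config.group2_overrides),
            "outputs": paths,
        }
        write_manifest(manifest, paths["manifest"])
    except ValidationError:
        raise
    return PipelineResult(
        out_dir=str(out), labels=labels, features=features, report=report, paths=paths
    )


def load_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in ("out_dir", "seed", "window_mode"):
        if key in raw:
            kwargs[key] = raw[key]
    if "thresholds" in raw:
        kwargs["thresholds"] = PsychThresholds(**raw["thresholds"])
    if "emg" in raw:
        kwargs["emg_params"] = EmgPreprocessParams(**raw["emg"])
    if "peaks" in raw:
        kwargs["peak_params"] = PeakParams(**raw["peaks"])
    if "simulate" in raw:
        sim = raw["simulate"] or {}
        kwargs["simulate"] = True
        if "n_group1" in sim:
            kwargs["n_group1"] = int(sim["n_group1"])
        if "n_group2" in sim:
            kwargs["n_group2"] = int(sim["n_group2"])
        kwargs["group1_overrides"] = dict(sim.get("group1", {}))
        kwargs["group2_overrides"] = dict(sim.get("group2", {}))
    elif "data" in raw:
        data = raw["data"]
        kwargs["simulate"] = False
        kwargs["participants_path"] = data.get("participants")
        kwargs["sessions"] = tuple(
            SessionInput(
                participant_id=int(s["participant_id"]),
                signals=s["signals"],
                events=s["events"],
                mvc=s["mvc"],
            )
            for s in data.get("sessions", [])
        )
    return PipelineConfig(**kwargs)
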