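"""Synthetic push-and-pull session generator.

The generator emulates the study protocol statistically: 5 series x 2
attempts (10 traversals) over an 8-waypoint circuit, 2 s pauses between
attempts and 20 s between series, ~8.9 s per waypoint-to-waypoint leg
(so a two-leg phase lasts ~17.7 s and a session ~11-12 min), everything
sampled at 100 Hz.

It is an invented statistical stand-in for real recordings, not a
biomechanical model: each handle side's resultant force is a baseline
plus one smooth exertion bump per interior waypoint, plus Poisson-count
"micro-peak" bumps, plus sensor noise, decomposed into three components
through a slowly wandering direction; EMG channels are band-limited
noise amplitude-modulated by the exertion envelope.  Every knob maps
one-to-one onto an extracted parameter so parameter recovery is the
test surface:

* ``effort_scale``      -> force amplitudes, hence window integrals;
* ``asymmetry``         -> right/left amplitude ratio;
* ``peak_timing_shift`` -> relative moment of the window maximum;
* ``micro_peak_rate``   -> expected extra local maxima per window;
* ``fatigue_drift``     -> log-linear per-traversal trend on amplitude
  and leg duration (negative = later traversals weaker and faster);
* ``emg_mav_targets``   -> MVC-normalized MAV per channel (generated
  channels are calibrated against the package's own preprocessing
  chain, so the configured targets hold by construction);
* ``mvc_values``        -> per-channel MVC amplitudes (same
  calibration).

One seed drives a documented stream split (schedule, per-side force,
direction, per-channel EMG, per-participant spawns), so adding a
participant never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal as sps

from .cohort import ParticipantRecord, PsychThresholds
from .exceptions import ValidationError
from .features import EMG_CHANNELS
from .signals import EmgPreprocessParams, design_bandpass, extract_mvc, preprocess_emg

__all__ = [
    "SimulationConfig",
    "SessionRecording",
    "MVCTrialSet",
    "SimulatedParticipant",
    "simulate_session",
    "simulate_mvc_trials",
    "simulate_cohort",
    "group1_reference_config",
    "group2_reference_config",
]

FORCE_CHANNELS = ("fxR", "fyR", "fzR", "fxL", "fyL", "fzL")

#: normalized MAV levels typical of a low-effort (reference-group) session
DEFAULT_MAV_TARGETS = {
    "back_left": 0.0064,
    "back_right": 0.0222,
    "chest_left": 0.0080,
    "chest_right": 0.0151,
    "arm_left": 0.0299,
    "arm_right": 0.0299,
}

#: normalized MAV levels typical of a high-effort session
HIGH_EFFORT_MAV_TARGETS = {
    "back_left": 0.0325,
    "back_right": 0.0339,
    "chest_left": 0.0186,
    "chest_right": 0.0185,
    "arm_left": 0.0422,
    "arm_right": 0.0422,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic session generator (defaults = study protocol)."""

    sample_rate: float = 100.0  # Hz
    n_series: int = 5
    attempts_per_series: int = 2
    inter_attempt_pause: float = 2.0  # s, within a series
    inter_series_pause: float = 20.0  # s, between series
    segment_duration_mean: float = 8.87  # s per waypoint-to-waypoint leg
    effort_scale: float = 1.0  # multiplies all force amplitudes
    asymmetry: float = 1.0  # right / left amplitude ratio
    peak_timing_shift: float = -0.15  # relative moment of the main force peak
    micro_peak_rate: float = 8.0  # expected extra local maxima per window
    fatigue_drift: float = 0.0  # log-linear per-traversal trend
    emg_mav_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MAV_TARGETS)
    )
    mvc_values: dict[str, float] = field(
        default_factory=lambda: {ch: 1.0 for ch in EMG_CHANNELS}
    )
    noise_sd: float = 0.05  # additive component noise, force units
    seed: int = 0
    # shape parameters of the exertion model
    base_force: float = 1.3  # baseline resultant level, force units
    bump_amplitude: float = 6.0  # main exertion bump height, force units
    bump_sigma: float = 1.0  # main bump width, s
    micro_amp_range: tuple[float, float] = (0.5, 1.2)  # force units
    micro_sigma_range: tuple[float, float] = (0.08, 0.20)  # s
    duration_cv: float = 0.08  # lognormal CV of leg durations
    amplitude_cv: float = 0.10  # lognormal CV of main bump heights
    vertical_fraction: float = 0.18  # share of the resultant along z
    lead_in: float = 1.0  # s of idle signal before/after the session
    mvc_trial_duration: float = 5.0  # s
    emg_params: EmgPreprocessParams = field(default_factory=EmgPreprocessParams)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValidationError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.n_series < 1 or self.attempts_per_series < 1:
            raise ValidationError("n_series and attempts_per_series must be >= 1")
        for name in ("effort_scale", "asymmetry", "segment_duration_mean"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.micro_peak_rate < 0:
            raise ValidationError("micro_peak_rate must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for ch, v in self.mvc_values.items():
            if not v > 0:
                raise ValidationError(f"mvc_values[{ch!r}] must be > 0, got {v}")
        for ch, v in self.emg_mav_targets.items():
            if not 0.0 < v < 1.0:
                raise ValidationError(
                    f"emg_mav_targets[{ch!r}] must be in (0, 1), got {v}"
                )

    @property
    def n_traversals(self) -> int:
        return self.n_series * self.attempts_per_series


@dataclass
class SessionRecording:
    """A uniformly sampled session: 6 force + 6 EMG channels + events."""

    time: np.ndarray  # s, uniform grid starting at 0
    sample_rate: float
    force: dict[str, np.ndarray]  # keys: fxR fyR fzR fxL fyL fzL
    emg: dict[str, np.ndarray]  # keys: EMG_CHANNELS
    events: pd.DataFrame  # columns: traversal, event_index, position, time
    meta: dict

    @property
    def n_samples(self) -> int:
        return self.time.size


@dataclass
class MVCTrialSet:
    """One maximal-voluntary-contraction trial per EMG channel."""

    time: np.ndarray
    sample_rate: float
    trials: dict[str, np.ndarray]


@dataclass
class SimulatedParticipant:
    record: ParticipantRecord
    recording: SessionRecording
    mvc_trials: MVCTrialSet


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal multipliers with the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size)
    s = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def _schedule(cfg: SimulationConfig, rng: np.random.Generator):
    """Event times and leg durations for every traversal."""
    traversals = []
    cursor = cfg.lead_in
    for trav in range(1, cfg.n_traversals + 1):
        fat = math.exp(cfg.fatigue_drift * (trav - 1))
        legs = cfg.segment_duration_mean * fat * _lognormal_factors(rng, cfg.duration_cv, 7)
        events = cursor + np.concatenate([[0.0], np.cumsum(legs)])
        traversals.append({"index": trav, "events": events, "legs": legs, "fatigue": fat})
        if trav < cfg.n_traversals:
            within_series = trav % cfg.attempts_per_series != 0
            cursor = events[-1] + (
                cfg.inter_attempt_pause if within_series else cfg.inter_series_pause
            )
    return traversals, traversals[-1]["events"][-1] + cfg.lead_in


def _activity_envelope(cfg, traversals, time):
    """Smooth 0..1 gate that is 1 while the cart is being moved."""
    ramp = 0.5  # s
    a = np.zeros_like(time)
    for tr in traversals:
        t0, t1 = tr["events"][0], tr["events"][-1]
        up = np.clip((time - (t0 - ramp)) / ramp, 0.0, 1.0)
        down = np.clip(((t1 + ramp) - time) / ramp, 0.0, 1.0)
        a = np.maximum(a, 0.5 * (1 - np.cos(np.pi * up)) * 0.5 * (1 - np.cos(np.pi * down)))
    return a


def _add_bump(out: np.ndarray, time: np.ndarray, center: float, amp: float,
              sigma: float, sample_rate: float) -> None:
    half = int(math.ceil(5 * sigma * sample_rate))
    ic = int(round(center * sample_rate))
    lo, hi = max(0, ic - half), min(time.size, ic + half + 1)
    if hi > lo:
        t = time[lo:hi]
        out[lo:hi] += amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _clean_force_side(cfg, traversals, time, activity, side_mult, rng):
    """Noise-free resultant magnitude for one side."""
    fs = cfg.sample_rate
    amp_gate = np.zeros_like(time)
    for tr in traversals:
        t0, t1 = tr["events"][0], tr["events"][-1]
        mask = (time >= t0 - 1.0) & (time <= t1 + 1.0)
        amp_gate[mask] = tr["fatigue"]
    f = cfg.base_force * cfg.effort_scale * side_mult * activity * amp_gate
    for tr in traversals:
        e, legs, fat = tr["events"], tr["legs"], tr["fatigue"]
        # one main exertion bump per interior waypoint (phase middles)
        for j in range(1, 7):
            if cfg.peak_timing_shift <= 0:
                shift = cfg.peak_timing_shift * 0.3 * legs[j - 1]
            else:
                shift = cfg.peak_timing_shift * 0.7 * legs[j]
            amp = (
                cfg.bump_amplitude
                * cfg.effort_scale
                * side_mult
                * fat
                * _lognormal_factors(rng, cfg.amplitude_cv, None)
            )
            _add_bump(f, time, e[j] + shift, float(amp), cfg.bump_sigma, fs)
        # micro-peaks: Poisson-count small bumps along each leg
        window_scale = cfg.segment_duration_mean * fat
        for j in range(7):
            lam = cfg.micro_peak_rate * legs[j] / window_scale
            count = rng.poisson(lam)
            for _ in range(count):
                c = rng.uniform(e[j], e[j + 1])
                amp = rng.uniform(*cfg.micro_amp_range) * cfg.effort_scale * side_mult * fat
                sig = rng.uniform(*cfg.micro_sigma_range)
                _add_bump(f, time, float(c), float(amp), float(sig), fs)
    return f


def _decompose(cfg, time, f_clean, rng):
    """Split a magnitude into three components + sensor noise."""
    cz = cfg.vertical_fraction + 0.03 * np.sin(2 * np.pi * 0.03 * time)
    theta0 = rng.uniform(0, 2 * np.pi)
    phi = 0.4 * np.sin(2 * np.pi * 0.05 * time + theta0)
    h = np.sqrt(1.0 - cz * cz)
    comps = (h * np.cos(phi), h * np.sin(phi), cz)
    return tuple(
        f_clean * c + rng.normal(0.0, cfg.noise_sd, time.size) for c in comps
    )


def _bandlimited_carrier(cfg, n, rng):
    sos = design_bandpass(cfg.sample_rate, cfg.emg_params)
    carrier = sps.sosfiltfilt(sos, rng.normal(0.0, 1.0, n))
    sd = carrier.std()
    return carrier / sd if sd > 0 else carrier


def _emg_channel(cfg, time, activity, f_clean, target, mvc, rng):
    """One raw EMG channel calibrated so the pipeline recovers ``target``.

    The channel is amplitude-modulated band-limited noise; after
    generating it, the package's own preprocessing chain is run on it
    and the raw trace rescaled so the mean MVC-normalized envelope over
    the active portion equals the configured MAV target exactly.
    """
    carrier = _bandlimited_carrier(cfg, time.size, rng)
    fmax = f_clean.max()
    mod = activity * (0.7 + (0.3 * f_clean / fmax if fmax > 0 else 0.0)) + 0.02
    raw = carrier * mod
    env = preprocess_emg(raw, cfg.sample_rate, cfg.emg_params)
    active = activity > 0.9
    current = float(np.mean(env[active])) / mvc if active.any() else 0.0
    if current <= 0:
        raise ValidationError("EMG calibration failed: zero active envelope")
    return raw * (target / current)


def simulate_session(config: SimulationConfig | None = None) -> SessionRecording:
    """Generate one seeded session recording.

    Deterministic given (config, seed): the seed is split into named
    child streams (schedule, force right/left, direction right/left,
    one per EMG channel) so channels do not interact.
    """
    cfg = config or SimulationConfig()
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(4 + len(EMG_CHANNELS))
    rng_sched, rng_fr, rng_fl, rng_dir = (np.random.default_rng(c) for c in children[:4])
    rng_emg = {ch: np.random.default_rng(c) for ch, c in zip(EMG_CHANNELS, children[4:])}

    traversals, total = _schedule(cfg, rng_sched)
    n = int(math.ceil(total * cfg.sample_rate)) + 1
    time = np.arange(n) / cfg.sample_rate
    activity = _activity_envelope(cfg, traversals, time)

    # right/left amplitude multipliers realise the configured ratio
    mult = {"right": cfg.asymmetry, "left": 1.0}
    f_clean = {
        "right": _clean_force_side(cfg, traversals, time, activity, mult["right"], rng_fr),
        "left": _clean_force_side(cfg, traversals, time, activity, mult["left"], rng_fl),
    }
    fxR, fyR, fzR = _decompose(cfg, time, f_clean["right"], rng_dir)
    fxL, fyL, fzL = _decompose(cfg, time, f_clean["left"], rng_dir)
    force = {"fxR": fxR, "fyR": fyR, "fzR": fzR, "fxL": fxL, "fyL": fyL, "fzL": fzL}

    emg = {}
    for ch in EMG_CHANNELS:
        side = "right" if ch.endswith("right") else "left"
        emg[ch] = _emg_channel(
            cfg,
            time,
            activity,
            f_clean[side],
            cfg.emg_mav_targets[ch],
            cfg.mvc_values[ch],
            rng_emg[ch],
        )

    rows = []
    from .segmentation import EXPECTED_POSITIONS

    for tr in traversals:
        for k, (pos, t_ev) in enumerate(zip(EXPECTED_POSITIONS, tr["events"]), start=1):
            rows.append(
                {"traversal": tr["index"], "event_index": k, "position": pos, "time": t_ev}
            )
    events = pd.DataFrame(rows)

    meta = {"seed": cfg.seed, "config": _config_dict(cfg)}
    return SessionRecording(
        time=time,
        sample_rate=cfg.sample_rate,
        force=force,
        emg=emg,
        events=events,
        meta=meta,
    )


def _config_dict(cfg: SimulationConfig) -> dict:
    from dataclasses import asdict

    d = asdict(cfg)
    d["emg_params"] = {
        "bandpass_low": cfg.emg_params.bandpass_low,
        "bandpass_high": cfg.emg_params.bandpass_high,
        "filter_order": cfg.emg_params.filter_order,
        "envelope_window": cfg.emg_params.envelope_window,
        "envelope_kind": cfg.emg_params.envelope_kind,
    }
    d["micro_amp_range"] = list(cfg.micro_amp_range)
    d["micro_sigma_range"] = list(cfg.micro_sigma_range)
    return d


def simulate_mvc_trials(config: SimulationConfig | None = None) -> MVCTrialSet:
    """Per-channel maximal-contraction trials.

    Each trial is a ramp-plateau-ramp burst of band-limited noise whose
    raw trace is rescaled so that the processed envelope maximum equals
    the configured MVC value exactly (whatever the noise realisation).
    """
    cfg = config or SimulationConfig()
    fs = cfg.sample_rate
    n = int(round(cfg.mvc_trial_duration * fs)) + 1
    time = np.arange(n) / fs
    ramp = min(1.0, cfg.mvc_trial_duration / 4)
    up = np.clip(time / ramp, 0, 1)
    down = np.clip((time[-1] - time) / ramp, 0, 1)
    profile = 0.5 * (1 - np.cos(np.pi * up)) * 0.5 * (1 - np.cos(np.pi * down))

    ss = np.random.SeedSequence([cfg.seed, 7])  # distinct from the session streams
    trials = {}
    for ch, child in zip(EMG_CHANNELS, ss.spawn(len(EMG_CHANNELS))):
        rng = np.random.default_rng(child)
        raw = _bandlimited_carrier(cfg, n, rng) * profile
        env = preprocess_emg(raw, fs, cfg.emg_params)
        peak = extract_mvc(env, fs, cfg.emg_params.envelope_window)
        trials[ch] = raw * (cfg.mvc_values[ch] / peak)
    return MVCTrialSet(time=time, sample_rate=fs, trials=trials)


# ---------------------------------------------------------------------------
# reference group configurations and cohort simulation

def group1_reference_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Low-score group: asymmetric, early peaks, fewer micro-peaks."""
    kw = dict(
        seed=seed,
        effort_scale=1.0,
        asymmetry=1.06,
        peak_timing_shift=-0.18,
        micro_peak_rate=8.3,
        fatigue_drift=-0.0064,
        segment_duration_mean=8.87,
        emg_mav_targets=dict(DEFAULT_MAV_TARGETS),
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def group2_reference_config(seed: int = 0, **overrides) -> SimulationConfig:
    """High-score group: symmetric, ~1.9x effort, slower, more micro-peaks."""
    kw = dict(
        seed=seed,
        effort_scale=1.9,
        asymmetry=1.0,
        peak_timing_shift=-0.10,
        micro_peak_rate=10.3,
        fatigue_drift=-0.021,
        # chosen so the drift-pooled mean leg duration sits ~2% above the
        # low-score group's, matching the published duration relation
        segment_duration_mean=9.69,
        emg_mav_targets=dict(HIGH_EFFORT_MAV_TARGETS),
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def _group1_record(pid: int, rng: np.random.Generator) -> ParticipantRecord:
    return ParticipantRecord(
        participant_id=pid,
        age=float(np.clip(rng.normal(35.0, 5.8), 20, 60)),
        weight=float(np.clip(rng.normal(94.9, 11.0), 60, 130)),
        height=float(np.clip(rng.normal(186.0, 8.8), 160, 210)),
        dass_stress_total=int(rng.integers(5, 13)),
        dass_anxiety_total=int(rng.integers(0, 7)),
        dass_depression_total=int(rng.integers(0, 8)),
        apathy_total=int(rng.integers(4, 13)),
        straight_leg_raise_positive=False,
        reduced_rom=False,
        trigger_point_count=0,
    )


def _group2_record(
    pid: int, rng: np.random.Generator, thresholds: PsychThresholds
) -> ParticipantRecord:
    low = {
        "stress": int(rng.integers(5, 13)),
        "anxiety": int(rng.integers(0, 7)),
        "depression": int(rng.integers(0, 8)),
        "apathy": int(rng.integers(4, 13)),
    }
    scores = dict(low)
    for scale in rng.choice(["stress", "anxiety", "depression", "apathy"], 2, replace=False):
        scores[scale] = getattr(thresholds, scale) + int(rng.integers(0, 5))
    return ParticipantRecord(
        participant_id=pid,
        age=float(np.clip(rng.normal(35.0, 5.8), 20, 60)),
        weight=float(np.clip(rng.normal(94.9, 11.0), 60, 130)),
        height=float(np.clip(rng.normal(186.0, 8.8), 160, 210)),
        dass_stress_total=scores["stress"],
        dass_anxiety_total=scores["anxiety"],
        dass_depression_total=scores["depression"],
        apathy_total=scores["apathy"],
        straight_leg_raise_positive=False,
        reduced_rom=True,
        trigger_point_count=int(rng.integers(2, 7)),
    )


def simulate_cohort(
    n_group1: int = 2,
    n_group2: int = 3,
    group1_config: SimulationConfig | None = None,
    group2_config: SimulationConfig | None = None,
    seed: int = 0,
    participant_effort_cv: float = 0.08,
) -> tuple[list[ParticipantRecord], dict[int, SimulatedParticipant]]:
    """Simulate a two-group cohort with per-participant jitter.

    Psychometric/clinical fields of the emitted records satisfy the
    corresponding group criteria by construction; each participant's
    recording is drawn from the group config with a lognormal jitter on
    ``effort_scale`` and an independent child seed.
    """
    if n_group1 < 1 or n_group2 < 1:
        raise ValidationError("both groups need at least one participant")
    g1 = group1_config or group1_reference_config()
    g2 = group2_config or group2_reference_config()
    thresholds = PsychThresholds()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_group1 + n_group2)

    records: list[ParticipantRecord] = []
    sessions: dict[int, SimulatedParticipant] = {}
    pid = 0
    for i in range(n_group1 + n_group2):
        pid += 1
        rng = np.random.default_rng(children[i])
        in_group1 = i < n_group1
        base = g1 if in_group1 else g2
        record = (
            _group1_record(pid, rng) if in_group1 else _group2_record(pid, rng, thresholds)
        )
        jitter = float(_lognormal_factors(rng, participant_effort_cv, None))
        child_seed = int(rng.integers(0, 2**31 - 1))
        cfg = replace(base, effort_scale=base.effort_scale * jitter, seed=child_seed)
        recording = simulate_session(cfg)
        mvc = simulate_mvc_trials(cfg)
        records.append(record)
        sessions[pid] = SimulatedParticipant(record=record, recording=recording, mvc_trials=mvc)
    return records, sessions
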