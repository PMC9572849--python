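"""Resultant-force and surface-EMG signal processing.

Force: each handle sensor reports three orthogonal components sampled
uniformly; the per-sample resultant magnitude is the Euclidean norm
``F = sqrt(fx^2 + fy^2 + fz^2)``.

EMG: raw channels are band-pass filtered (zero phase), full-wave
rectified and smoothed into an amplitude envelope; each channel is then
normalized to that muscle's maximal voluntary contraction (MVC), taken
as the maximum of the identically processed MVC-trial envelope so that
numerator and denominator pass through the same chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import ValidationError

__all__ = [
    "EmgPreprocessParams",
    "force_magnitude",
    "preprocess_emg",
    "extract_mvc",
    "normalize_emg",
    "mav",
]

#: factor of Nyquist beyond which the band-pass upper edge is clipped
_NYQUIST_CLIP = 0.95


@dataclass(frozen=True)
class EmgPreprocessParams:
    """Knobs of the EMG conditioning chain.

    ``bandpass_low``/``bandpass_high`` are the pass-band edges in Hz
    (the upper edge is clipped below Nyquist when the sampling rate is
    too low to honour it); ``filter_order`` is the overall band-pass
    order (even); ``envelope_window`` is the smoothing window in
    seconds; ``envelope_kind`` selects moving-average-of-rectified
    (``"mav"``) or RMS (``"rms"``) envelopes.
    """

    bandpass_low: float = 20.0
    bandpass_high: float = 450.0
    filter_order: int = 4
    envelope_window: float = 0.1
    envelope_kind: str = "mav"

    def __post_init__(self) -> None:
        if not 0 < self.bandpass_low < self.bandpass_high:
            raise ValidationError(
                f"need 0 < bandpass_low < bandpass_high, got "
                f"({self.bandpass_low}, {self.bandpass_high})"
            )
        if self.filter_order < 2 or self.filter_order % 2:
            raise ValidationError(
                f"filter_order must be a positive even integer, got {self.filter_order}"
            )
        if self.envelope_window <= 0:
            raise ValidationError("envelope_window must be > 0")
        if self.envelope_kind not in ("mav", "rms"):
            raise ValidationError(
                f"envelope_kind must be 'mav' or 'rms', got {self.envelope_kind!r}"
            )


def force_magnitude(fx, fy, fz) -> np.ndarray:
    """Per-sample resultant magnitude of a three-component force signal."""
    fx = np.asarray(fx, dtype=float)
    fy = np.asarray(fy, dtype=float)
    fz = np.asarray(fz, dtype=float)
    if not (fx.shape == fy.shape == fz.shape):
        raise ValidationError(
            f"force component lengths differ: {fx.shape}, {fy.shape}, {fz.shape}"
        )
    return np.sqrt(fx * fx + fy * fy + fz * fz)


def design_bandpass(sample_rate: float, params: EmgPreprocessParams) -> np.ndarray:
    """Second-order sections of the zero-phase band-pass used throughout."""
    if sample_rate <= 0:
        raise ValidationError(f"sample_rate must be > 0, got {sample_rate}")
    nyq = sample_rate / 2.0
    if sample_rate <= 2.0 * params.bandpass_low:
        raise ValidationError(
            f"sample_rate {sample_rate} Hz too low for band-pass lower edge "
            f"{params.bandpass_low} Hz"
        )
    high = params.bandpass_high
    if high >= nyq:
        high = _NYQUIST_CLIP * nyq
        warnings.warn(
            f"band-pass upper edge {params.bandpass_high} Hz is at/above Nyquist "
            f"({nyq} Hz); clipped to {high} Hz",
            stacklevel=3,
        )
    return sps.butter(
        params.filter_order // 2,
        [params.bandpass_low, high],
        btype="bandpass",
        fs=sample_rate,
        output="sos",
    )


def _envelope(rectified_or_squared: np.ndarray, n: int, rms: bool) -> np.ndarray:
    kernel = np.ones(n) / n
    smoothed = np.convolve(rectified_or_squared, kernel, mode="same")
    if rms:
        return np.sqrt(np.maximum(smoothed, 0.0))
    return smoothed


def preprocess_emg(
    raw,
    sample_rate: float,
    params: EmgPreprocessParams | None = None,
) -> np.ndarray:
    """Band-pass, rectify and smooth one raw EMG channel into an envelope.

    The filter is applied forward-backward (zero phase); the envelope is
    a sliding-window moving average of the rectified signal (or sliding
    RMS).  Output is non-negative and the same length as the input.
    """
    params = params or EmgPreprocessParams()
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1:
        raise ValidationError(f"expected a 1-D channel, got shape {raw.shape}")
    sos = design_bandpass(sample_rate, params)
    try:
        filtered = sps.sosfiltfilt(sos, raw)
    except ValueError as exc:
        raise ValidationError(
            f"EMG series too short ({raw.size} samples) for zero-phase filtering: {exc}"
        ) from None
    n = max(1, int(round(params.envelope_window * sample_rate)))
    if params.envelope_kind == "rms":
        return _envelope(filtered**2, n, rms=True)
    return _envelope(np.abs(filtered), n, rms=False)


def extract_mvc(
    envelope,
    sample_rate: float,
    envelope_window: float = 0.1,
) -> float:
    """Maximum of a processed MVC-trial envelope.

    The first and last ``envelope_window`` seconds are excluded so filter
    and smoothing transients cannot masquerade as the contraction peak.
    """
    envelope = np.asarray(envelope, dtype=float)
    if envelope.size == 0:
        raise ValidationError("empty MVC trial envelope")
    k = int(round(envelope_window * sample_rate))
    trimmed = envelope[k:-k] if envelope.size > 2 * k and k > 0 else envelope
    value = float(np.max(trimmed))
    if value <= 0:
        raise ValidationError("MVC must be strictly positive; trial envelope is all zero")
    return value


def normalize_emg(envelope, mvc: float) -> np.ndarray:
    """Express an EMG envelope as a fraction of the muscle's MVC."""
    if not mvc > 0:
        raise ValidationError(f"MVC must be > 0, got {mvc}")
    return np.asarray(envelope, dtype=float) / float(mvc)


def mav(segment) -> float:
    """Mean absolute value of a windowed series."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValidationError("MAV of an empty segment is undefined")
    return float(np.mean(np.abs(segment)))
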