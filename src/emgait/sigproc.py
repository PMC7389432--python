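"""Raw sEMG → normalized linear envelopes.

The chain is the standard one for gait EMG: linear-phase FIR high-pass at
20 Hz (motion artifact) and low-pass at 450 Hz (high-frequency noise),
full-wave rectification, second-order Butterworth low-pass at 5 Hz applied
forward and backward (zero net phase shift, so envelope peaks stay aligned
with the underlying bursts), then per-channel min–max normalization into
[0, 1] within each subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, fftconvolve, firwin, sosfiltfilt

from .exceptions import (
    DegenerateSignalError,
    ParameterError,
    SignalLengthError,
)
from .synthdata import CHANNEL_NAMES, SubjectRecording


@dataclass
class EnvelopeSet:
    """Normalized [0, 1] envelopes on the same timeline as the recording."""

    subject_id: str
    sampling_rate: float
    envelopes: np.ndarray  # (10, n_samples), values in [0, 1]
    normalization_bounds: list[tuple[float, float]]  # per-channel (min, max)

    @property
    def n_samples(self) -> int:
        return self.envelopes.shape[1]

    @property
    def n_channels(self) -> int:
        return self.envelopes.shape[0]


def bandpass_raw(
    signal: np.ndarray,
    sampling_rate: float,
    hp_cutoff: float = 20.0,
    lp_cutoff: float = 450.0,
    fir_order: int = 250,
) -> np.ndarray:
    """High-pass then low-pass the raw sEMG with linear-phase FIR filters.

    Two Hamming-window FIR filters of the given order (order+1 taps each)
    are applied as a cascade, centered so the symmetric filters' group
    delay is compensated and the output stays time-aligned with the input.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if sampling_rate <= 2 * lp_cutoff:
        raise ParameterError(
            "sampling_rate must exceed twice the low-pass cutoff"
        )
    if len(signal) <= fir_order + 1:
        raise SignalLengthError(
            f"signal length {len(signal)} too short for an order-"
            f"{fir_order} FIR filter"
        )
    numtaps = fir_order + 1  # odd taps: type-I, valid for a high-pass
    hp = firwin(numtaps, hp_cutoff, pass_zero=False, fs=sampling_rate)
    lp = firwin(numtaps, lp_cutoff, pass_zero=True, fs=sampling_rate)
    out = fftconvolve(signal, hp, mode="same")
    out = fftconvolve(out, lp, mode="same")
    return out


def extract_envelope(
    filtered: np.ndarray,
    sampling_rate: float,
    env_cutoff: float = 5.0,
) -> np.ndarray:
    """Full-wave rectification + zero-phase 2nd-order Butterworth low-pass.

    The Butterworth filter is run forward and backward (zero net phase
    shift, effectively 4th-order magnitude), so a symmetric burst's
    envelope peaks at the burst center.  DC gain is exactly 1.  Tiny
    negative undershoots from the IIR filter are clipped at 0.
    """
    if sampling_rate <= 2 * env_cutoff:
        raise ParameterError(
            "sampling_rate must exceed twice the envelope cutoff"
        )
    rectified = np.abs(np.asarray(filtered, dtype=np.float64))
    sos = butter(2, env_cutoff, btype="low", fs=sampling_rate, output="sos")
    envelope = sosfiltfilt(sos, rectified)
    return np.clip(envelope, 0.0, None)


def minmax_normalize(
    envelope: np.ndarray,
    bounds: tuple[float, float] | None = None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Map an envelope into [0, 1]; returns the (min, max) bounds used.

    Pass precomputed ``bounds`` to reuse a previous scaling (values are
    then clipped into [0, 1]).  A constant channel has no dynamic range and
    raises ``DegenerateSignalError``.
    """
    envelope = np.asarray(envelope, dtype=np.float64)
    if envelope.size == 0:
        raise ParameterError("cannot normalize an empty sequence")
    if bounds is None:
        lo, hi = float(envelope.min()), float(envelope.max())
    else:
        lo, hi = bounds
    if hi <= lo:
        raise DegenerateSignalError(
            "constant channel: min == max, normalization undefined"
        )
    out = (envelope - lo) / (hi - lo)
    if bounds is not None:
        out = np.clip(out, 0.0, 1.0)
    return out, (lo, hi)


def preprocess_recording(
    rec: SubjectRecording,
    hp_cutoff: float = 20.0,
    lp_cutoff: float = 450.0,
    env_cutoff: float = 5.0,
    fir_order: int = 250,
    bounds: list[tuple[float, float]] | None = None,
) -> EnvelopeSet:
    """Run the full chain over all ten channels, preserving channel order.

    By default normalization bounds come from each channel's own full
    recording (subject-level normalization); pass ``bounds`` to reuse, for
    example, bounds computed on a training portion only.
    """
    envelopes = np.empty_like(rec.channels)
    out_bounds: list[tuple[float, float]] = []
    for i, name in enumerate(CHANNEL_NAMES):
        try:
            filt = bandpass_raw(
                rec.channels[i],
                rec.sampling_rate,
                hp_cutoff,
                lp_cutoff,
                fir_order,
            )
            env = extract_envelope(filt, rec.sampling_rate, env_cutoff)
            envelopes[i], b = minmax_normalize(
                env, None if bounds is None else bounds[i]
            )
            out_bounds.append(b)
        except (DegenerateSignalError, SignalLengthError) as exc:
            raise type(exc)(f"channel {name}: {exc}") from exc
    return EnvelopeSet(
        subject_id=rec.subject_id,
        sampling_rate=rec.sampling_rate,
        envelopes=envelopes,
        normalization_bounds=out_bounds,
    )
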