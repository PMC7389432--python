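"""Synthetic gait and surface-EMG generator.

Emulates a ~5-minute barefoot walk recorded at 2 kHz with five sEMG probes
per leg (tibialis anterior TA, gastrocnemius lateralis GL, medial hamstrings
MH, vastus lateralis VL, rectus femoris RF) plus one binary foot–floor-
contact ("basographic") signal per leg, 0 = stance, 1 = swing.

The gait timeline is a sequence of strides whose durations follow a
truncated normal law; within each stride the stance phase occupies a
fraction of the cycle drawn around 60% (the canonical healthy stance/swing
split).  Per-muscle activation envelopes are sums of Gaussian bursts in
cycle-fraction coordinates, phase-locked to the gait cycle of the muscle's
leg; the raw-like sEMG is that envelope (plus a noise floor) amplitude-
modulating a zero-mean carrier band-limited to 20–450 Hz.  The right leg
walks half a cycle out of phase with the left, as in real contralateral
gait, so both legs' channels carry usable phase information.

Everything is deterministic under the seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, firwin

from .events import EventSeries, detect_events
from .exceptions import ParameterError

#: Fixed channel order: right leg then left leg, five muscles each.
CHANNEL_NAMES = (
    "R_TA", "R_GL", "R_MH", "R_VL", "R_RF",
    "L_TA", "L_GL", "L_MH", "L_VL", "L_RF",
)

LEGS = ("right", "left")


@dataclass
class Burst:
    """One activation burst: a Gaussian bump in cycle-fraction coordinates.

    ``center`` is the position within the gait cycle (0 = heel-strike of the
    muscle's own leg), ``width`` the Gaussian sigma in cycle fractions, and
    ``amplitude`` an arbitrary activation scale.  The bump is truncated at
    ±3 sigma and wraps around the cycle boundary.
    """

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.center < 1.0:
            raise ParameterError(f"burst center {self.center} not in [0, 1)")
        if self.width <= 0 or self.amplitude < 0:
            raise ParameterError("burst width must be > 0, amplitude >= 0")


def default_muscle_profiles() -> dict[str, list[Burst]]:
    """Activation timing typical of healthy level walking.

    Cycle fraction 0 is the leg's own heel-strike; stance occupies roughly
    [0, 0.6).  TA fires at loading response and again during swing for foot
    clearance; GL in mid/terminal stance (push-off); MH in terminal swing
    through early stance; VL at loading response; RF at loading response and
    again around toe-off.
    """
    per_muscle = {
        "TA": [Burst(0.02, 0.035, 1.0), Burst(0.70, 0.060, 0.9)],
        "GL": [Burst(0.42, 0.060, 1.0)],
        "MH": [Burst(0.93, 0.045, 0.9), Burst(0.04, 0.040, 0.6)],
        "VL": [Burst(0.06, 0.045, 1.0)],
        "RF": [Burst(0.05, 0.040, 0.7), Burst(0.60, 0.045, 0.6)],
    }
    return {
        name: [copy.copy(b) for b in per_muscle[name.split("_")[1]]]
        for name in CHANNEL_NAMES
    }


@dataclass
class GaitSimParams:
    """Parameters of the synthetic walk.

    Defaults emulate a ~5-minute self-paced walk of a healthy adult: stride
    duration 1100 ± 60 ms, stance fraction 0.60 ± 0.02, sEMG carrier band
    20–450 Hz, sampling rate 2 kHz.
    """

    duration_s: float = 300.0
    sampling_rate: float = 2000.0
    stride_mean_ms: float = 1100.0
    stride_sd_ms: float = 60.0
    stance_fraction_mean: float = 0.60
    stance_fraction_sd: float = 0.02
    muscle_profiles: dict[str, list[Burst]] = field(
        default_factory=default_muscle_profiles
    )
    carrier_band: tuple[float, float] = (20.0, 450.0)
    noise_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        if not 0.0 < self.stance_fraction_mean < 1.0:
            raise ParameterError("stance_fraction_mean must be in (0, 1)")
        if self.stride_sd_ms < 0 or self.stance_fraction_sd < 0:
            raise ParameterError("standard deviations must be >= 0")
        if self.stride_mean_ms <= 0:
            raise ParameterError("stride_mean_ms must be positive")
        if set(self.muscle_profiles) != set(CHANNEL_NAMES):
            raise ParameterError(
                "muscle_profiles must define exactly one burst list per "
                f"channel {CHANNEL_NAMES}"
            )
        if not 0 < self.carrier_band[0] < self.carrier_band[1]:
            raise ParameterError("carrier_band must be an increasing Hz pair")
        if self.noise_floor < 0:
            raise ParameterError("noise_floor must be >= 0")


@dataclass
class SubjectRecording:
    """One subject's synchronized recording: the unit of all protocols."""

    subject_id: str
    sampling_rate: float
    channels: np.ndarray  # (10, n_samples), CHANNEL_NAMES order
    basographic: dict[str, np.ndarray]  # leg -> binary (0 stance, 1 swing)
    truth_events: dict[str, EventSeries] | None = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.shape[0] != len(CHANNEL_NAMES):
            raise ParameterError(
                f"expected {len(CHANNEL_NAMES)} channels, "
                f"got {self.channels.shape[0]}"
            )
        n = self.channels.shape[1]
        for leg, baso in self.basographic.items():
            baso = np.asarray(baso)
            if baso.shape != (n,):
                raise ParameterError(
                    f"basographic[{leg}] length {baso.shape} != {n}"
                )
            if not np.isin(baso, (0, 1)).all():
                raise ParameterError("basographic values must be 0 or 1")
            self.basographic[leg] = baso.astype(np.uint8)

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    n_sigma: float = 3.0,
    lo: float | None = None,
    hi: float | None = None,
) -> float:
    """One draw from N(mean, sd) truncated at ±n_sigma and clipped bounds."""
    if sd == 0:
        return mean
    lo_t = mean - n_sigma * sd if lo is None else max(lo, mean - n_sigma * sd)
    hi_t = mean + n_sigma * sd if hi is None else min(hi, mean + n_sigma * sd)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo_t <= x <= hi_t:
            return x
    return float(np.clip(mean, lo_t, hi_t))


def _draw_strides(
    params: GaitSimParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw complete strides filling the requested duration.

    Returns (stride lengths in samples, stance fractions).  Strides are
    appended until the next would overrun the duration; the final partial
    stride is dropped, so the recording spans whole strides.
    """
    total = int(round(params.duration_s * params.sampling_rate))
    lengths, fracs = [], []
    used = 0
    while True:
        stride_ms = _truncated_normal(
            rng, params.stride_mean_ms, params.stride_sd_ms
        )
        stride = int(round(stride_ms * params.sampling_rate / 1000.0))
        if stride <= 1:
            raise ParameterError("stride duration collapsed to <= 1 sample")
        if used + stride > total:
            break
        frac = _truncated_normal(
            rng,
            params.stance_fraction_mean,
            params.stance_fraction_sd,
            lo=0.45,
            hi=0.75,
        )
        lengths.append(stride)
        fracs.append(frac)
        used += stride
    if not lengths:
        raise ParameterError(
            "duration shorter than a single stride; nothing to generate"
        )
    return np.array(lengths), np.array(fracs)


def _phase_arrays(
    stride_lengths: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample cycle fraction and stride index for the reference leg."""
    n = int(stride_lengths.sum())
    phase = np.empty(n)
    stride_idx = np.empty(n, dtype=np.int64)
    pos = 0
    for k, length in enumerate(stride_lengths):
        phase[pos : pos + length] = np.arange(length) / length
        stride_idx[pos : pos + length] = k
        pos += length
    return phase, stride_idx


def _basographic_from_phase(
    phase: np.ndarray,
    stride_idx: np.ndarray,
    stance_fracs: np.ndarray,
    phase_offset: float,
) -> np.ndarray:
    leg_phase = (phase + phase_offset) % 1.0
    return (leg_phase >= stance_fracs[stride_idx]).astype(np.uint8)


def generate_timeline(
    params: GaitSimParams, phase_offset: float = 0.0
) -> tuple[np.ndarray, EventSeries]:
    """Generate one leg's foot–floor-contact signal and its true events.

    The signal alternates stance (0) and swing (1) runs; with zero phase
    offset it starts at a heel-strike and contains complete strides only.
    Heel-strikes are 1→0 transitions, toe-offs 0→1 transitions; both are
    recovered by run-length reading the signal itself, so decoding the
    basographic signal reproduces the truth events exactly.
    """
    rng = np.random.default_rng(params.seed)
    lengths, fracs = _draw_strides(params, rng)
    phase, stride_idx = _phase_arrays(lengths)
    baso = _basographic_from_phase(phase, stride_idx, fracs, phase_offset)
    truth = detect_events(baso, params.sampling_rate, leg="left")
    return baso, truth


def _bandlimited_carrier(
    n: int,
    sampling_rate: float,
    band: tuple[float, float],
    rng: np.random.Generator,
    numtaps: int = 513,
) -> np.ndarray:
    """Unit-variance zero-mean noise band-limited to ``band`` Hz."""
    white = rng.standard_normal(n)
    taps = firwin(
        numtaps, list(band), pass_zero=False, fs=sampling_rate
    )
    carrier = fftconvolve(white, taps, mode="same")
    carrier -= carrier.mean()
    sd = carrier.std()
    if sd > 0:
        carrier /= sd
    return carrier


def _envelope_from_bursts(
    leg_phase: np.ndarray, bursts: list[Burst]
) -> np.ndarray:
    env = np.zeros_like(leg_phase)
    for b in bursts:
        d = (leg_phase - b.center + 0.5) % 1.0 - 0.5  # wrapped distance
        bump = np.where(
            np.abs(d) <= 3.0 * b.width,
            b.amplitude * np.exp(-0.5 * (d / b.width) ** 2),
            0.0,
        )
        env += bump
    return env


def generate_emg(
    timeline: np.ndarray,
    params: GaitSimParams,
    timeline_right: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Raw-like sEMG for all ten channels, phase-locked to the timeline(s).

    ``timeline`` drives the left-leg muscles; ``timeline_right`` (defaults
    to the same signal) drives the right-leg muscles.  The cycle phase is
    reconstructed from each leg's heel-strikes, each channel's activation
    envelope is the sum of its bursts, and the output is
    ``(noise_floor + envelope) * carrier`` with a zero-mean carrier
    band-limited to ``params.carrier_band``.
    """
    timeline = np.asarray(timeline)
    if timeline_right is None:
        timeline_right = timeline
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    n = len(timeline)
    leg_phase = {
        "left": _phase_from_basographic(timeline),
        "right": _phase_from_basographic(np.asarray(timeline_right)),
    }
    channels = np.empty((len(CHANNEL_NAMES), n))
    for i, name in enumerate(CHANNEL_NAMES):
        bursts = params.muscle_profiles[name]
        if not bursts:
            raise ParameterError(f"channel {name} has an empty burst list")
        leg = "right" if name.startswith("R_") else "left"
        env = _envelope_from_bursts(leg_phase[leg], bursts)
        carrier = _bandlimited_carrier(
            n, params.sampling_rate, params.carrier_band, rng
        )
        channels[i] = (params.noise_floor + env) * carrier
    return channels


def _phase_from_basographic(baso: np.ndarray) -> np.ndarray:
    """Cycle fraction per sample, 0 at each heel-strike of this leg.

    Strides are delimited by consecutive heel-strikes (1→0 transitions).
    The leading and trailing partial segments are extrapolated with the
    duration of the adjacent stride.
    """
    d = np.diff(baso.astype(np.int8))
    hs = np.flatnonzero(d == -1) + 1
    n = len(baso)
    phase = np.empty(n)
    if len(hs) == 0:
        # no heel-strike: treat the whole record as a single cycle
        phase[:] = np.arange(n) / n
        return phase
    for a, b in zip(hs[:-1], hs[1:]):
        phase[a:b] = np.arange(b - a) / (b - a)
    first_d = (hs[1] - hs[0]) if len(hs) > 1 else n
    lead = np.arange(-hs[0], 0)
    phase[: hs[0]] = (lead / first_d) % 1.0
    last_d = (hs[-1] - hs[-2]) if len(hs) > 1 else n
    tail = np.arange(n - hs[-1])
    phase[hs[-1] :] = (tail / last_d) % 1.0
    return phase


def generate_subject(
    params: GaitSimParams, subject_id: str = "S1"
) -> SubjectRecording:
    """A full synthetic subject: both legs' timelines, events, and sEMG.

    The right leg walks half a cycle ahead of the left, as in contralateral
    gait; both legs share the stride schedule but draw independent stance
    fractions.
    """
    rng = np.random.default_rng(params.seed)
    lengths, fracs_left = _draw_strides(params, rng)
    fracs_right = np.array(
        [
            _truncated_normal(
                rng,
                params.stance_fraction_mean,
                params.stance_fraction_sd,
                lo=0.45,
                hi=0.75,
            )
            for _ in lengths
        ]
    )
    phase, stride_idx = _phase_arrays(lengths)
    baso = {
        "left": _basographic_from_phase(phase, stride_idx, fracs_left, 0.0),
        "right": _basographic_from_phase(phase, stride_idx, fracs_right, 0.5),
    }
    truth = {
        leg: detect_events(baso[leg], params.sampling_rate, leg=leg)
        for leg in LEGS
    }
    channels = generate_emg(
        baso["left"], params, timeline_right=baso["right"], rng=rng
    )
    return SubjectRecording(
        subject_id=subject_id,
        sampling_rate=params.sampling_rate,
        channels=channels,
        basographic=baso,
        truth_events=truth,
    )


def generate_population(
    n_subjects: int,
    base: GaitSimParams,
    heterogeneity: float = 0.3,
    seed: int = 0,
    return_params: bool = False,
):
    """Generate a cohort with between-subject variability.

    Each subject's stride statistics, stance fraction, burst centers and
    amplitudes are jittered around ``base`` with magnitude proportional to
    ``heterogeneity`` (0 → identical parameters, signals differing only by
    carrier noise).  With heterogeneity > 0, inter-subject variability of
    activation timing exceeds the within-subject stride-to-stride
    variability, which is what makes leave-one-subject-out harder than
    within-subject cross-validation.
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    if heterogeneity < 0:
        raise ParameterError("heterogeneity must be >= 0")
    rng = np.random.default_rng(seed)
    subjects = []
    all_params = []
    for i in range(n_subjects):
        p = copy.deepcopy(base)
        h = heterogeneity
        p.stride_mean_ms = float(
            np.clip(
                base.stride_mean_ms * (1.0 + h * rng.normal(0, 0.08)),
                400.0,
                None,
            )
        )
        p.stance_fraction_mean = float(
            np.clip(
                base.stance_fraction_mean + h * rng.normal(0, 0.03),
                0.50,
                0.70,
            )
        )
        for bursts in p.muscle_profiles.values():
            for b in bursts:
                b.center = float((b.center + h * rng.normal(0, 0.05)) % 1.0)
                b.amplitude = float(b.amplitude * np.exp(h * rng.normal(0, 0.3)))
        p.seed = int(rng.integers(0, 2**31 - 1))
        all_params.append(p)
        subjects.append(generate_subject(p, subject_id=f"S{i + 1}"))
    if return_params:
        return subjects, all_params
    return subjects
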