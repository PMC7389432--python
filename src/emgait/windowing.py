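"""Window construction: envelopes + basographic signal → network inputs.

Each channel is split into non-overlapping 20-sample windows (10 ms at
2 kHz); the ten synchronized windows are interleaved channel-fastest into a
single 200-sample vector.  A window whose basographic samples are all 0
(or all 1) is labeled stance (or swing); windows straddling a phase
transition are flagged in a mask — they are excluded from classifier
training and accuracy, but still receive a prediction when reconstructing
the foot–floor-contact signal for event detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError, SignalLengthError
from .sigproc import EnvelopeSet


@dataclass
class WindowDataset:
    """Interleaved window vectors with labels and a transition mask.

    ``labels[i]`` is meaningful only where ``transition_mask[i]`` is False
    (masked entries are set to -1).  ``window_start`` are sample indices of
    each window's first sample; windows tile the timeline without overlap.
    """

    vectors: np.ndarray  # (n_windows, window_len * n_channels)
    labels: np.ndarray  # int8: 0 stance, 1 swing, -1 masked
    transition_mask: np.ndarray  # bool
    window_start: np.ndarray  # int64 sample indices
    window_len: int
    n_channels: int
    target_leg: str = "left"

    @property
    def n_windows(self) -> int:
        return self.vectors.shape[0]

    def labeled_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.transition_mask)


def interleave_windows(
    env: EnvelopeSet | np.ndarray, window_len: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Build channel-interleaved window vectors.

    Within a window, vector position ``t * n_channels + m`` holds sample
    ``t`` of channel ``m``: the first vector starts with sample 0 of
    channel 0, then sample 0 of channel 1, and so on.  Trailing samples
    that do not fill a window are discarded.
    """
    channels = env.envelopes if isinstance(env, EnvelopeSet) else np.asarray(env)
    if channels.ndim != 2:
        raise ParameterError("expected a (n_channels, n_samples) array")
    n_channels, n_samples = channels.shape
    n_windows = n_samples // window_len
    if n_windows == 0:
        raise SignalLengthError(
            f"{n_samples} samples < one window of {window_len}"
        )
    trimmed = channels[:, : n_windows * window_len]
    # (C, W, L) -> (W, L, C) -> (W, L*C): channel-fastest interleaving
    vectors = (
        trimmed.reshape(n_channels, n_windows, window_len)
        .transpose(1, 2, 0)
        .reshape(n_windows, window_len * n_channels)
    )
    window_start = np.arange(n_windows, dtype=np.int64) * window_len
    return np.ascontiguousarray(vectors), window_start


def deinterleave_windows(
    vectors: np.ndarray, window_len: int, n_channels: int
) -> np.ndarray:
    """Inverse of :func:`interleave_windows` (exact round trip)."""
    vectors = np.asarray(vectors)
    n_windows = vectors.shape[0]
    return (
        vectors.reshape(n_windows, window_len, n_channels)
        .transpose(2, 0, 1)
        .reshape(n_channels, n_windows * window_len)
    )


def label_windows(
    basographic: np.ndarray,
    window_start: np.ndarray,
    window_len: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Label each window stance/swing, masking phase-transition windows.

    A window is labeled 0 (1) iff every basographic sample inside it is
    0 (1); mixed windows get label -1 and a True transition mask.
    """
    basographic = np.asarray(basographic)
    if not np.isin(basographic, (0, 1)).all():
        raise ParameterError("basographic values must be 0 or 1")
    window_start = np.asarray(window_start)
    if window_start[-1] + window_len > len(basographic):
        raise ParameterError("basographic signal does not cover all windows")
    segs = np.stack(
        [basographic[s : s + window_len] for s in window_start]
    )
    all0 = (segs == 0).all(axis=1)
    all1 = (segs == 1).all(axis=1)
    labels = np.full(len(window_start), -1, dtype=np.int8)
    labels[all0] = 0
    labels[all1] = 1
    mask = ~(all0 | all1)
    return labels, mask


def build_dataset(
    env: EnvelopeSet,
    basographic: np.ndarray,
    target_leg: str = "left",
    window_len: int = 20,
) -> WindowDataset:
    """Convenience composition: interleave + label for one target leg."""
    vectors, window_start = interleave_windows(env, window_len)
    labels, mask = label_windows(basographic, window_start, window_len)
    return WindowDataset(
        vectors=vectors,
        labels=labels,
        transition_mask=mask,
        window_start=window_start,
        window_len=window_len,
        n_channels=env.n_channels,
        target_leg=target_leg,
    )


def split_slots(
    ds: WindowDataset | int, k: int = 10
) -> list[tuple[int, int]]:
    """Split the chronological window sequence into k contiguous slots.

    Returns k disjoint, exhaustive (start, stop) window-index ranges whose
    sizes differ by at most one window, in chronological order.
    """
    n_windows = ds if isinstance(ds, int) else ds.n_windows
    if k < 2:
        raise ParameterError("need at least 2 slots")
    if n_windows < k:
        raise ParameterError(f"{n_windows} windows cannot fill {k} slots")
    base, extra = divmod(n_windows, k)
    ranges = []
    start = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        ranges.append((start, start + size))
        start += size
    return ranges
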