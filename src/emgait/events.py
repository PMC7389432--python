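"""Gait-event extraction and tolerance-based scoring.

The classifier emits one stance/swing label per window.  Chronologically
arranging those labels reconstructs a predicted foot–floor-contact signal in
which runs of 0 (stance) alternate with runs of 1 (swing).  Spurious short
phases — "spikes" produced by isolated misclassified windows — are merged
away, heel-strikes (swing→stance) and toe-offs (stance→swing) are read off
the cleaned signal, and predictions are paired with ground-truth events under
a temporal tolerance to yield precision, recall, F1 and the mean absolute
timing error (MAE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError

HS = "HS"
TO = "TO"


@dataclass
class EventSeries:
    """Ordered heel-strike / toe-off events for one leg.

    Times are sample indices (0-based) into the recording; millisecond
    values are derived through ``sampling_rate``.  Types must alternate and
    times must be strictly increasing.
    """

    leg: str
    times: np.ndarray  # sample indices, int64
    types: list[str]  # "HS" / "TO", parallel to times
    sampling_rate: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        if len(self.times) != len(self.types):
            raise ParameterError("times and types must have equal length")
        if len(self.times) > 1:
            if not np.all(np.diff(self.times) > 0):
                raise ParameterError("event times must be strictly increasing")
            for a, b in zip(self.types, self.types[1:]):
                if a == b:
                    raise ParameterError("event types must alternate")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def times_ms(self) -> np.ndarray:
        return self.times * 1000.0 / self.sampling_rate

    def of_type(self, event_type: str) -> np.ndarray:
        """Times (ms) of all events of one type."""
        keep = [i for i, t in enumerate(self.types) if t == event_type]
        return self.times_ms[keep]

    def restrict(self, start_sample: int, stop_sample: int) -> "EventSeries":
        """Events with start_sample <= time < stop_sample."""
        keep = [
            i
            for i, t in enumerate(self.times)
            if start_sample <= t < stop_sample
        ]
        return EventSeries(
            leg=self.leg,
            times=self.times[keep],
            types=[self.types[i] for i in keep],
            sampling_rate=self.sampling_rate,
        )

    def shift(self, offset_samples: int) -> "EventSeries":
        return EventSeries(
            leg=self.leg,
            times=self.times + int(offset_samples),
            types=list(self.types),
            sampling_rate=self.sampling_rate,
        )


@dataclass
class MatchResult:
    """One-to-one pairing of predicted and truth events of a single type.

    Every pair satisfies |t_g - t_p| < tolerance_ms strictly; unmatched
    predictions are false positives, unmatched truth events false negatives.
    All times in milliseconds.
    """

    event_type: str
    tolerance_ms: float
    pairs: list[tuple[float, float]]  # (predicted, truth)
    false_positives: list[float]
    false_negatives: list[float]

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.false_positives)

    @property
    def fn(self) -> int:
        return len(self.false_negatives)

    @property
    def errors_ms(self) -> np.ndarray:
        return np.array([abs(g - p) for p, g in self.pairs])


@dataclass
class EventScore:
    """Precision/recall/F1 and MAE for one event type.

    Undefined metrics (empty denominators) are ``None``, never silently 0.
    """

    event_type: str
    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    f1: float | None
    mae_ms: float | None


@dataclass
class EvaluationReport:
    """Full evaluation of one predicted foot–floor-contact signal."""

    accuracy: float | None
    hs: EventScore | None
    to: EventScore | None
    spikes_removed: int = 0
    mean_spike_duration_ms: float | None = None
    extra: dict = field(default_factory=dict)


def reconstruct_basographic(
    labels: np.ndarray,
    window_start: np.ndarray | None = None,
    window_len: int = 20,
) -> np.ndarray:
    """Expand per-window binary labels into a sample-rate contact signal.

    Each window's label fills its ``window_len`` samples.  Transition
    windows carry the model's prediction like any other window: at event
    time every window is predicted.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ParameterError("no window labels to reconstruct from")
    if not np.isin(labels, (0, 1)).all():
        raise ParameterError("labels must be binary (0/1)")
    if window_start is not None:
        window_start = np.asarray(window_start)
        expected = np.arange(len(labels)) * window_len + window_start[0]
        if not np.array_equal(window_start, expected):
            raise ParameterError("windows must tile the timeline without gaps")
    return np.repeat(labels.astype(np.uint8), window_len)


def remove_short_phases(
    signal: np.ndarray,
    sampling_rate: float,
    min_duration_ms: float = 175.0,
) -> tuple[np.ndarray, list[int]]:
    """Reject phases shorter than ``min_duration_ms`` (spikes).

    Scanning left to right, any run strictly shorter than the minimum is
    merged into the preceding run (the first run merges forward into its
    successor), and the scan repeats until no run before the last violates
    the minimum.  The trailing run is exempt: it is usually a truncated
    phase, not a spike.  Runs of exactly the minimum duration are kept.

    Returns the cleaned signal and the lengths (samples) of removed runs.
    """
    signal = np.asarray(signal).astype(np.uint8)
    if signal.size == 0:
        return signal, []
    min_len = int(round(min_duration_ms * sampling_rate / 1000.0))

    # run-length encode once; afterwards operate on the run list
    change = np.flatnonzero(np.diff(signal)) + 1
    bounds = np.concatenate(([0], change, [signal.size]))
    runs: list[list[int]] = [
        [int(signal[b]), int(e - b)] for b, e in zip(bounds[:-1], bounds[1:])
    ]

    removed: list[int] = []
    while True:
        idx = next(
            (i for i in range(len(runs) - 1) if runs[i][1] < min_len), None
        )
        if idx is None:
            break
        _, length = runs.pop(idx)
        removed.append(length)
        if idx == 0:
            runs[0][1] += length
        else:
            runs[idx - 1][1] += length
            if idx < len(runs) and runs[idx][0] == runs[idx - 1][0]:
                runs[idx - 1][1] += runs[idx][1]
                runs.pop(idx)

    cleaned = np.concatenate(
        [np.full(length, value, dtype=np.uint8) for value, length in runs]
    )
    return cleaned, removed


def detect_events(
    signal: np.ndarray, sampling_rate: float, leg: str = "left"
) -> EventSeries:
    """Read heel-strikes (1→0) and toe-offs (0→1) off a binary signal.

    The event time is the first sample of the new phase.  A constant signal
    yields an empty series.
    """
    signal = np.asarray(signal).astype(np.int8)
    d = np.diff(signal)
    idx = np.flatnonzero(d) + 1
    types = [HS if d[i - 1] < 0 else TO for i in idx]
    return EventSeries(
        leg=leg, times=idx, types=types, sampling_rate=sampling_rate
    )


def match_events(
    predicted: EventSeries,
    truth: EventSeries,
    tolerance_ms: float = 600.0,
) -> dict[str, MatchResult]:
    """Pair predicted with truth events of the same type within tolerance.

    Greedy chronological one-to-one matching: each predicted event, in
    order, takes the nearest still-unmatched truth event of its type with
    |t_g - t_p| < T (strict).  For healthy gait, where same-type events are
    ~1 stride apart and T is well below a stride, this coincides with the
    optimal assignment.
    """
    results = {}
    for event_type in (HS, TO):
        pred_t = predicted.of_type(event_type)
        truth_t = truth.of_type(event_type)
        taken = np.zeros(len(truth_t), dtype=bool)
        pairs: list[tuple[float, float]] = []
        fps: list[float] = []
        for tp_ms in pred_t:
            best, best_err = None, tolerance_ms
            for j, tg_ms in enumerate(truth_t):
                if taken[j]:
                    continue
                err = abs(tg_ms - tp_ms)
                if err < best_err:
                    best, best_err = j, err
            if best is None:
                fps.append(float(tp_ms))
            else:
                taken[best] = True
                pairs.append((float(tp_ms), float(truth_t[best])))
        fns = [float(t) for j, t in enumerate(truth_t) if not taken[j]]
        results[event_type] = MatchResult(
            event_type=event_type,
            tolerance_ms=tolerance_ms,
            pairs=pairs,
            false_positives=fps,
            false_negatives=fns,
        )
    return results


def score(match: MatchResult) -> EventScore:
    """Precision, recall, F1 and MAE from a match result.

    precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2·precision·recall/(precision+recall),
    MAE = mean |t_g - t_p| over matched pairs (ms).
    Empty denominators yield None.
    """
    tp, fp, fn = match.tp, match.fp, match.fn
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision is None or recall is None:
        f1 = None
    else:
        f1 = 0.0
    mae = float(np.mean(match.errors_ms)) if tp > 0 else None
    return EventScore(
        event_type=match.event_type,
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        mae_ms=mae,
    )
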