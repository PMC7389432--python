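"""Experimental protocols: intra-subject 10-fold and leave-one-subject-out.

Intra-subject: one subject's chronological window sequence is split into
10 contiguous slots; each fold trains on 9 slots (with the chronological
tail of that training sequence held out for early stopping) and tests on
the remaining slot.  Inter-subject: the classifier trains on all subjects
but one and tests on the held-out subject.  Both report stance/swing
accuracy and heel-strike / toe-off timing metrics, aggregated as
mean ± SD, and the two approaches are compared metric-by-metric with a
Shapiro–Wilk normality gate followed by a t test or Kruskal–Wallis.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import events as ev
from .config import StudyConfig
from .exceptions import DegenerateTrainingError, ParameterError
from .model import (
    MLPConfig,
    classification_accuracy,
    init_model,
    predict_labels,
    train,
)
from .sigproc import preprocess_recording
from .synthdata import SubjectRecording
from .windowing import WindowDataset, build_dataset, split_slots


@dataclass
class FoldReport:
    """Results of one train/test fold."""

    fold: int
    test_range: tuple[int, int]  # window indices [start, stop)
    n_train_windows: int
    train_accuracy: float
    test_accuracy: float
    hs: ev.EventScore
    to: ev.EventScore
    spikes_removed: int
    mean_spike_duration_ms: float | None
    best_epoch: int
    epochs_run: int


@dataclass
class SubjectReport:
    """Per-subject results: fold list plus mean ± SD summaries."""

    subject_id: str
    protocol: str  # "intra" | "inter"
    folds: list[FoldReport]
    summary: dict[str, tuple[float | None, float | None]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if not self.summary:
            self.summary = summarize_folds(self.folds)


@dataclass
class StudyReport:
    """Population-level results over all subjects of one protocol."""

    protocol: str
    subjects: list[SubjectReport]
    population: dict[str, tuple[float | None, float | None]]
    config: dict


@dataclass
class ComparisonResult:
    """Outcome of the statistical comparison of one metric across groups."""

    metric: str
    normality_p: tuple[float | None, float | None]
    test_used: str  # "t-test" | "kruskal-wallis"
    p_value: float
    significant: bool
    alpha: float = 0.05


_METRICS = (
    "train_accuracy",
    "test_accuracy",
    "hs_precision",
    "hs_recall",
    "hs_f1",
    "hs_mae_ms",
    "to_precision",
    "to_recall",
    "to_f1",
    "to_mae_ms",
)


def fold_metrics(fold: FoldReport) -> dict[str, float | None]:
    return {
        "train_accuracy": fold.train_accuracy,
        "test_accuracy": fold.test_accuracy,
        "hs_precision": fold.hs.precision,
        "hs_recall": fold.hs.recall,
        "hs_f1": fold.hs.f1,
        "hs_mae_ms": fold.hs.mae_ms,
        "to_precision": fold.to.precision,
        "to_recall": fold.to.recall,
        "to_f1": fold.to.f1,
        "to_mae_ms": fold.to.mae_ms,
    }


def _mean_sd(values: list[float | None]) -> tuple[float | None, float | None]:
    vals = [v for v in values if v is not None]
    if not vals:
        return None, None
    return float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


def summarize_folds(
    folds: list[FoldReport],
) -> dict[str, tuple[float | None, float | None]]:
    per = [fold_metrics(f) for f in folds]
    return {m: _mean_sd([p[m] for p in per]) for m in _METRICS}


def _summarize_subjects(
    subjects: list[SubjectReport],
) -> dict[str, tuple[float | None, float | None]]:
    return {
        m: _mean_sd([s.summary[m][0] for s in subjects]) for m in _METRICS
    }


def _fold_seed(master: int, *keys: int) -> int:
    return int(
        np.random.SeedSequence([master, *keys]).generate_state(1)[0]
        % (2**31 - 1)
    )


def _truth_events(rec: SubjectRecording, leg: str) -> ev.EventSeries:
    if rec.truth_events and leg in rec.truth_events:
        return rec.truth_events[leg]
    return ev.detect_events(rec.basographic[leg], rec.sampling_rate, leg=leg)


def prepare_subject(
    rec: SubjectRecording, cfg: StudyConfig
) -> WindowDataset:
    """Envelope extraction + windowing for the configured target leg."""
    env = preprocess_recording(
        rec,
        hp_cutoff=cfg.hp_cutoff,
        lp_cutoff=cfg.lp_cutoff,
        env_cutoff=cfg.env_cutoff,
        fir_order=cfg.fir_order,
    )
    return build_dataset(
        env,
        rec.basographic[cfg.target_leg],
        target_leg=cfg.target_leg,
        window_len=cfg.window_len,
    )


def _assert_disjoint(train_idx: np.ndarray, test_idx: np.ndarray) -> None:
    if np.intersect1d(train_idx, test_idx).size:
        raise RuntimeError(
            "protocol hygiene violation: test windows leaked into training"
        )


def _evaluate_events(
    pred_labels: np.ndarray,
    offset_windows: int,
    truth: ev.EventSeries,
    cfg: StudyConfig,
) -> tuple[ev.EventScore, ev.EventScore, int, float | None]:
    """Score events reconstructed from predicted labels of one segment."""
    signal = ev.reconstruct_basographic(pred_labels, window_len=cfg.window_len)
    cleaned, spikes = ev.remove_short_phases(
        signal, cfg.sampling_rate, cfg.min_phase_ms
    )
    offset = offset_windows * cfg.window_len
    predicted = ev.detect_events(cleaned, cfg.sampling_rate, leg=truth.leg)
    predicted = predicted.shift(offset)
    truth_seg = truth.restrict(offset, offset + len(signal))
    matches = ev.match_events(predicted, truth_seg, cfg.tolerance_ms)
    mean_spike = (
        float(np.mean(spikes) * 1000.0 / cfg.sampling_rate)
        if spikes
        else None
    )
    return (
        ev.score(matches[ev.HS]),
        ev.score(matches[ev.TO]),
        len(spikes),
        mean_spike,
    )


def _run_fold(
    fold: int,
    ds: WindowDataset,
    train_idx: np.ndarray,
    test_range: tuple[int, int],
    truth: ev.EventSeries,
    cfg: StudyConfig,
    mlp_cfg: MLPConfig,
    test_ds: WindowDataset | None = None,
) -> FoldReport:
    """Train on labeled windows of ``train_idx``; test on ``test_range``.

    ``test_ds`` defaults to ``ds`` (intra-subject); the inter-subject
    protocol passes the held-out subject's dataset instead.
    """
    test_ds = ds if test_ds is None else test_ds
    ts, te = test_range
    labeled = train_idx[~ds.transition_mask[train_idx]]
    state = init_model(mlp_cfg)
    trained = train(state, ds.vectors[labeled], ds.labels[labeled], mlp_cfg)

    _, train_pred = predict_labels(trained, ds.vectors[labeled])
    train_acc = classification_accuracy(train_pred, ds.labels[labeled])

    _, test_pred = predict_labels(trained, test_ds.vectors[ts:te])
    test_acc = classification_accuracy(
        test_pred,
        test_ds.labels[ts:te],
        mask=test_ds.transition_mask[ts:te],
    )
    hs, to, n_spikes, mean_spike = _evaluate_events(
        test_pred, ts, truth, cfg
    )
    return FoldReport(
        fold=fold,
        test_range=test_range,
        n_train_windows=len(labeled),
        train_accuracy=train_acc,
        test_accuracy=test_acc,
        hs=hs,
        to=to,
        spikes_removed=n_spikes,
        mean_spike_duration_ms=mean_spike,
        best_epoch=trained.best_epoch,
        epochs_run=trained.epochs_run,
    )


def run_intra_subject(
    rec: SubjectRecording,
    cfg: StudyConfig,
    dataset: WindowDataset | None = None,
) -> SubjectReport:
    """10-fold cross-validation over contiguous slots of one subject.

    Each fold trains on nine slots (chronological order preserved; the tail
    ``val_fraction`` of that sequence is the early-stopping validation set)
    and tests on the held-out slot.  Folds whose training windows contain a
    single class are skipped with a warning.
    """
    ds = prepare_subject(rec, cfg) if dataset is None else dataset
    truth = _truth_events(rec, cfg.target_leg)
    slots = split_slots(ds, cfg.k_folds)
    folds: list[FoldReport] = []
    for fold, (ts, te) in enumerate(slots):
        train_idx = np.concatenate(
            [np.arange(s, e) for s, e in slots if (s, e) != (ts, te)]
        )
        _assert_disjoint(train_idx, np.arange(ts, te))
        mlp_cfg = dataclasses.replace(
            cfg.mlp, seed=_fold_seed(cfg.seed, fold)
        )
        try:
            folds.append(
                _run_fold(fold, ds, train_idx, (ts, te), truth, cfg, mlp_cfg)
            )
        except DegenerateTrainingError as exc:
            warnings.warn(
                f"fold {fold} of {rec.subject_id} skipped: {exc}",
                stacklevel=2,
            )
    if not folds:
        raise DegenerateTrainingError(
            f"all folds of {rec.subject_id} were degenerate"
        )
    return SubjectReport(
        subject_id=rec.subject_id, protocol="intra", folds=folds
    )


def run_intra_population(
    recs: list[SubjectRecording], cfg: StudyConfig
) -> StudyReport:
    """Intra-subject protocol applied to every subject of a cohort."""
    subjects = [run_intra_subject(rec, cfg) for rec in recs]
    return StudyReport(
        protocol="intra",
        subjects=subjects,
        population=_summarize_subjects(subjects),
        config=_config_snapshot(cfg),
    )


def run_inter_subject(
    recs: list[SubjectRecording],
    cfg: StudyConfig,
    datasets: list[WindowDataset] | None = None,
) -> StudyReport:
    """Leave-one-subject-out cross-validation over a cohort.

    Fold i trains on the concatenated window sequences of all subjects
    except i (validation = chronological tail of that concatenation) and
    tests on the whole recording of subject i.
    """
    if len(recs) < 2:
        raise ParameterError("inter-subject protocol needs >= 2 subjects")
    if datasets is None:
        datasets = [prepare_subject(rec, cfg) for rec in recs]
    subjects: list[SubjectReport] = []
    for i, rec in enumerate(recs):
        test_ds = datasets[i]
        truth = _truth_events(rec, cfg.target_leg)
        train_vectors = []
        train_labels = []
        for j, other in enumerate(datasets):
            if j == i:
                continue
            keep = other.labeled_indices()
            train_vectors.append(other.vectors[keep])
            train_labels.append(other.labels[keep])
        vectors = np.concatenate(train_vectors)
        labels = np.concatenate(train_labels)
        mlp_cfg = dataclasses.replace(cfg.mlp, seed=_fold_seed(cfg.seed, i))
        state = init_model(mlp_cfg)
        trained = train(state, vectors, labels, mlp_cfg)

        _, train_pred = predict_labels(trained, vectors)
        train_acc = classification_accuracy(train_pred, labels)
        _, test_pred = predict_labels(trained, test_ds.vectors)
        test_acc = classification_accuracy(
            test_pred, test_ds.labels, mask=test_ds.transition_mask
        )
        hs, to, n_spikes, mean_spike = _evaluate_events(
            test_pred, 0, truth, cfg
        )
        fold = FoldReport(
            fold=i,
            test_range=(0, test_ds.n_windows),
            n_train_windows=len(labels),
            train_accuracy=train_acc,
            test_accuracy=test_acc,
            hs=hs,
            to=to,
            spikes_removed=n_spikes,
            mean_spike_duration_ms=mean_spike,
            best_epoch=trained.best_epoch,
            epochs_run=trained.epochs_run,
        )
        subjects.append(
            SubjectReport(
                subject_id=rec.subject_id, protocol="inter", folds=[fold]
            )
        )
    return StudyReport(
        protocol="inter",
        subjects=subjects,
        population=_summarize_subjects(subjects),
        config=_config_snapshot(cfg),
    )


def compare_approaches(
    values_a: list[float],
    values_b: list[float],
    metric: str = "",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Compare one metric between two groups of per-subject values.

    Shapiro–Wilk assesses normality of each group; if both are compatible
    with normality at the 5% level, a two-tailed unpaired t test is used,
    otherwise Kruskal–Wallis.  Constant groups (normality undefined) fall
    back to Kruskal–Wallis with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ParameterError("each group needs at least 3 values")

    def _shapiro_p(x: np.ndarray) -> float | None:
        if np.ptp(x) == 0:
            return None
        return float(stats.shapiro(x).pvalue)

    pa, pb = _shapiro_p(a), _shapiro_p(b)
    if pa is None or pb is None:
        warnings.warn(
            "constant group: normality undefined, using Kruskal-Wallis",
            stacklevel=2,
        )
        normal = False
    else:
        normal = pa > alpha and pb > alpha
    if normal:
        test_used = "t-test"
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    else:
        test_used = "kruskal-wallis"
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0  # all values identical across both groups
        else:
            p = float(stats.kruskal(a, b).pvalue)
    return ComparisonResult(
        metric=metric,
        normality_p=(pa, pb),
        test_used=test_used,
        p_value=p,
        significant=bool(p < alpha),
        alpha=alpha,
    )


def _config_snapshot(cfg: StudyConfig) -> dict:
    snap = dataclasses.asdict(cfg)
    snap["channel_order"] = list(cfg.channel_order)
    return snap
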