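"""Event extraction and scoring, validated against brute-force oracles."""

import itertools

import numpy as np
import pytest

from emgait import (
    EventSeries,
    MatchResult,
    ParameterError,
    detect_events,
    match_events,
    reconstruct_basographic,
    remove_short_phases,
    score,
)

FS = 2000.0


def runs_to_signal(runs):
    return np.concatenate(
        [np.full(n, v, dtype=np.uint8) for v, n in runs]
    )


def oracle_remove_short(signal, min_len):
    """Independent re-derivation of spike removal on raw sample arrays.

    Each pass re-encodes the signal from scratch, finds the leftmost run
    (other than the last) shorter than the minimum, and overwrites its
    samples with the neighbour's value (the first run copies its
    successor); repeats until no such run remains.
    """
    signal = np.asarray(signal).astype(np.uint8).copy()
    removed = []
    while True:
        change = np.flatnonzero(np.diff(signal)) + 1
        bounds = np.concatenate(([0], change, [len(signal)]))
        found = False
        for i in range(len(bounds) - 2):  # exclude the trailing run
            b, e = bounds[i], bounds[i + 1]
            if e - b < min_len:
                fill = signal[b - 1] if b > 0 else signal[e]
                removed.append(e - b)
                signal[b:e] = fill
                found = True
                break
        if not found:
            return signal, removed


def event_series(times_ms, types, leg="left"):
    return EventSeries(
        leg=leg,
        times=np.round(np.asarray(times_ms) * FS / 1000).astype(np.int64),
        types=list(types),
        sampling_rate=FS,
    )


def oracle_best_matching(pred_ms, truth_ms, tol):
    """Exhaustive optimal one-to-one assignment under strict tolerance."""
    best_pairs, best_cost = 0, np.inf
    k = min(len(pred_ms), len(truth_ms))
    for size in range(k, -1, -1):
        if size < best_pairs:
            break
        for p_sub in itertools.combinations(range(len(pred_ms)), size):
            for t_perm in itertools.permutations(range(len(truth_ms)), size):
                errs = [
                    abs(truth_ms[t] - pred_ms[p])
                    for p, t in zip(p_sub, t_perm)
                ]
                if any(e >= tol for e in errs):
                    continue
                cost = sum(errs)
                if size > best_pairs or (
                    size == best_pairs and cost < best_cost
                ):
                    best_pairs, best_cost = size, cost
        if best_pairs == size:
            break
    return best_pairs


class TestReconstruct:
    def test_labels_expand_to_windows(self):
        signal = reconstruct_basographic(np.array([0, 0, 1, 1]), window_len=20)
        assert len(signal) == 80
        assert (signal[:40] == 0).all() and (signal[40:] == 1).all()

    def test_empty_labels_error(self):
        with pytest.raises(ParameterError):
            reconstruct_basographic(np.array([]))

    def test_gapped_window_starts_error(self):
        with pytest.raises(ParameterError):
            reconstruct_basographic(
                np.array([0, 1]), window_start=np.array([0, 40]), window_len=20
            )


class TestRemoveShortPhases:
    def test_interior_spike_merged_into_preceding(self):
        signal = runs_to_signal([(0, 500), (1, 300), (0, 700)])
        cleaned, removed = remove_short_phases(signal, FS)
        assert (cleaned == 0).all() and len(cleaned) == 1500
        assert removed == [300]

    def test_exact_minimum_duration_kept(self):
        signal = runs_to_signal([(0, 500), (1, 350), (0, 700)])
        cleaned, removed = remove_short_phases(signal, FS)
        assert np.array_equal(cleaned, signal)
        assert removed == []

    def test_clean_signal_is_fixed_point(self):
        signal = runs_to_signal([(0, 1200), (1, 800), (0, 1200), (1, 800)])
        cleaned, removed = remove_short_phases(signal, FS)
        assert np.array_equal(cleaned, signal)
        assert removed == []

    def test_idempotent(self, rng):
        signal = (rng.random(4000) < 0.5).astype(np.uint8)
        once, _ = remove_short_phases(signal, FS)
        twice, removed = remove_short_phases(once, FS)
        assert np.array_equal(once, twice)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(10, 5000))
            # mix of fine-grained noise and longer phases
            p = rng.uniform(0.02, 0.5)
            signal = (rng.random(n) < p).astype(np.uint8)
            got, removed = remove_short_phases(signal, FS, 175.0)
            want, want_removed = oracle_remove_short(signal, 350)
            assert np.array_equal(got, want)
            assert removed == want_removed

    def test_no_interior_run_below_minimum_after_cleaning(self, rng):
        signal = (rng.random(6000) < 0.3).astype(np.uint8)
        cleaned, _ = remove_short_phases(signal, FS)
        change = np.flatnonzero(np.diff(cleaned)) + 1
        bounds = np.concatenate(([0], change, [len(cleaned)]))
        lengths = np.diff(bounds)
        assert (lengths[:-1] >= 350).all()


class TestDetectEvents:
    def test_hs_and_to_positions(self):
        signal = runs_to_signal([(1, 400), (0, 800), (1, 400)])
        series = detect_events(signal, FS)
        assert series.types == ["HS", "TO"]
        assert series.times.tolist() == [400, 1200]
        assert np.allclose(series.times_ms, [200.0, 600.0])

    def test_constant_signal_yields_empty_series(self):
        series = detect_events(np.zeros(1000, dtype=np.uint8), FS)
        assert len(series) == 0

    def test_types_alternate_on_any_signal(self, rng):
        signal = (rng.random(3000) < 0.4).astype(np.uint8)
        cleaned, _ = remove_short_phases(signal, FS)
        series = detect_events(cleaned, FS)
        assert all(
            a != b for a, b in zip(series.types, series.types[1:])
        )


class TestMatchEvents:
    def test_pairing_with_extra_truth_events(self):
        pred = event_series([1000, 1600, 2200], ["HS", "TO", "HS"])
        truth = event_series(
            [1010, 1590, 2190, 2600, 3000], ["HS", "TO", "HS", "TO", "HS"]
        )
        result = match_events(pred, truth, 600.0)
        assert result["HS"].tp == 2
        assert result["HS"].fp == 0
        assert result["HS"].fn == 1  # truth HS at 3000 ms unmatched
        assert result["TO"].tp == 1 and result["TO"].fn == 1

    def test_beyond_tolerance_is_fp_and_fn(self):
        pred = event_series([1700], ["HS"])
        truth = event_series([1000], ["HS"])
        result = match_events(pred, truth, 600.0)["HS"]
        assert result.tp == 0 and result.fp == 1 and result.fn == 1

    def test_exact_tolerance_not_a_pair(self):
        pred = event_series([1600], ["HS"])
        truth = event_series([1000], ["HS"])
        result = match_events(pred, truth, 600.0)["HS"]
        assert result.tp == 0 and result.fp == 1 and result.fn == 1

    def test_greedy_agrees_with_optimal_assignment(self):
        """Pair counts equal exhaustive optimal matching on gait-like data.

        With same-type events about a stride (~1 s) apart and tolerances at
        or below 600 ms, greedy nearest-neighbour and the exhaustive optimal
        assignment coincide; instances have <= 6 events per side.
        """
        rng = np.random.default_rng(7)
        for _ in range(200):
            truth = gait_like_series(rng, n_strides=int(rng.integers(1, 4)))
            pred = jittered_prediction(rng, truth)
            tol = float(rng.choice([50.0, 600.0]))
            got = match_events(pred, truth, tol)
            for event_type in ("HS", "TO"):
                want = oracle_best_matching(
                    pred.of_type(event_type), truth.of_type(event_type), tol
                )
                assert got[event_type].tp == want


def gait_like_series(rng, n_strides):
    """Alternating HS/TO with stride-like spacing (~1.1 s, 60% stance)."""
    times, types = [], []
    t = float(rng.uniform(0, 500))
    for _ in range(n_strides):
        stride = rng.uniform(900, 1300)
        times += [t, t + 0.6 * stride]
        types += ["HS", "TO"]
        t += stride
    samples = np.round(np.asarray(times) * FS / 1000).astype(np.int64)
    return EventSeries("left", samples, types, FS)


def jittered_prediction(rng, truth):
    """Truth times perturbed by bounded timing noise, some events dropped."""
    keep_t, keep_y = [], []
    for t, typ in zip(truth.times, truth.types):
        if rng.random() < 0.15:  # missed event
            continue
        jitter = float(np.clip(rng.normal(0, 120), -150, 150))
        keep_t.append(t + int(round(jitter * FS / 1000)))
        keep_y.append(typ)
    if not keep_t:
        keep_t, keep_y = [int(truth.times[0])], [truth.types[0]]
    # dropping events breaks alternation; rebuild a valid alternating list
    order = np.argsort(keep_t)
    times, types = [], []
    for i in order:
        if types and types[-1] == keep_y[i]:
            continue
        times.append(keep_t[i])
        types.append(keep_y[i])
    return EventSeries("left", np.asarray(times), types, FS)


class TestScore:
    def test_eqs_from_counts(self):
        m = MatchResult(
            "HS", 600.0, [(0.0, 10.0)] * 9, [1.0], [2.0, 3.0, 4.0]
        )
        s = score(m)
        assert s.precision == pytest.approx(0.9)
        assert s.recall == pytest.approx(0.75)
        assert s.f1 == pytest.approx(2 * 0.9 * 0.75 / 1.65)

    def test_mae_mean_of_pair_errors(self):
        m = MatchResult("TO", 600.0, [(100.0, 110.0), (200.0, 190.0)], [], [])
        assert score(m).mae_ms == pytest.approx(10.0)

    def test_perfect_prediction(self):
        m = MatchResult("HS", 600.0, [(0.0, 0.0)] * 5, [], [])
        s = score(m)
        assert s.precision == s.recall == s.f1 == 1.0

    def test_undefined_metrics_are_none(self):
        m = MatchResult("HS", 600.0, [], [], [1.0])
        s = score(m)
        assert s.precision is None and s.mae_ms is None
        assert s.recall == 0.0
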