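"""Synthetic gait/EMG generator: timing statistics, determinism, spectra."""

import numpy as np
import pytest

from emgait import (
    Burst,
    CHANNEL_NAMES,
    GaitSimParams,
    ParameterError,
    default_muscle_profiles,
    generate_emg,
    generate_population,
    generate_subject,
    generate_timeline,
)


def run_lengths(signal):
    change = np.flatnonzero(np.diff(signal)) + 1
    bounds = np.concatenate(([0], change, [len(signal)]))
    return signal[bounds[:-1]], np.diff(bounds)


class TestTimeline:
    def test_zero_variance_strides_are_exact(self):
        p = GaitSimParams(
            duration_s=10.0,
            stride_mean_ms=1000.0,
            stride_sd_ms=0.0,
            stance_fraction_sd=0.0,
            seed=1,
        )
        baso, truth = generate_timeline(p)
        values, lengths = run_lengths(baso)
        assert len(baso) == 20000
        assert list(values) == [0, 1] * 10
        assert all(lengths[0::2] == 1200) and all(lengths[1::2] == 800)

    def test_default_stride_count_and_stance_fraction(self):
        p = GaitSimParams(seed=1)  # 300 s defaults
        baso, truth = generate_timeline(p)
        n_strides = int(np.sum(np.array(truth.types) == "HS")) + 1
        assert 240 <= n_strides <= 310
        assert abs(np.mean(baso == 0) - 0.60) <= 0.02

    def test_same_seed_is_bit_identical(self):
        p = GaitSimParams(duration_s=20.0, seed=7)
        b1, e1 = generate_timeline(p)
        b2, e2 = generate_timeline(p)
        assert np.array_equal(b1, b2)
        assert np.array_equal(e1.times, e2.times) and e1.types == e2.types

    def test_run_length_decoding_reproduces_truth_events(self):
        baso, truth = generate_timeline(GaitSimParams(duration_s=30, seed=3))
        values, lengths = run_lengths(baso)
        transitions = np.cumsum(lengths)[:-1]
        assert np.array_equal(transitions, truth.times)
        expected = ["TO" if v == 1 else "HS" for v in values[1:]]
        assert expected == truth.types

    def test_invalid_params_raise(self):
        with pytest.raises(ParameterError):
            GaitSimParams(duration_s=-1)
        with pytest.raises(ParameterError):
            GaitSimParams(sampling_rate=0)
        with pytest.raises(ParameterError):
            GaitSimParams(stance_fraction_mean=1.5)
        with pytest.raises(ParameterError):
            Burst(center=1.2, width=0.05, amplitude=1.0)


class TestEmg:
    def test_channel_count_and_length(self):
        p = GaitSimParams(duration_s=10, seed=2)
        baso, _ = generate_timeline(p)
        channels = generate_emg(baso, p)
        assert channels.shape == (10, len(baso))

    def test_zero_amplitudes_leave_noise_floor_only(self):
        p = GaitSimParams(duration_s=10, seed=2)
        for bursts in p.muscle_profiles.values():
            for b in bursts:
                b.amplitude = 0.0
        baso, _ = generate_timeline(p)
        channels = generate_emg(baso, p)
        # pure carrier scaled by noise_floor: unit-variance carrier * 0.05
        sds = channels.std(axis=1)
        assert np.allclose(sds, p.noise_floor, rtol=0.05)

    def test_swing_burst_energy_dominates_swing_phase(self):
        """A single burst centered in swing puts its energy into swing."""
        p = GaitSimParams(duration_s=60, seed=1, noise_floor=0.0)
        for name, bursts in p.muscle_profiles.items():
            bursts.clear()
            bursts.append(Burst(center=0.78, width=0.04, amplitude=1.0))
        baso, truth = generate_timeline(p)
        channels = generate_emg(baso, p)
        sig = np.abs(channels[CHANNEL_NAMES.index("L_TA")])
        hs = truth.times[np.array(truth.types) == "HS"]
        wins = 0
        for a, b in zip(hs[:-1], hs[1:]):
            stance = baso[a:b] == 0
            e_st = sig[a:b][stance].sum() / max(stance.sum(), 1)
            e_sw = sig[a:b][~stance].sum() / max((~stance).sum(), 1)
            wins += e_sw > e_st
        assert wins >= 0.95 * (len(hs) - 1)

    def test_empty_profile_errors(self):
        p = GaitSimParams(duration_s=10, seed=2)
        p.muscle_profiles["R_TA"] = []
        baso, _ = generate_timeline(p)
        with pytest.raises(ParameterError, match="R_TA"):
            generate_emg(baso, p)

    def test_carrier_band_limited(self):
        """< 5% of carrier power outside the 20-450 Hz band."""
        from emgait.synthdata import _bandlimited_carrier

        rng = np.random.default_rng(5)
        x = _bandlimited_carrier(2**16, 2000.0, (20.0, 450.0), rng)
        freqs = np.fft.rfftfreq(len(x), d=1 / 2000.0)
        power = np.abs(np.fft.rfft(x)) ** 2
        out_of_band = (freqs < 20.0) | (freqs > 450.0)
        assert power[out_of_band].sum() / power.sum() < 0.05


class TestSubjectAndPopulation:
    def test_subject_structure(self, short_subject):
        rec = short_subject
        n = rec.n_samples
        assert rec.channels.shape == (10, n)
        for leg in ("left", "right"):
            assert rec.basographic[leg].shape == (n,)
            assert set(np.unique(rec.basographic[leg])) <= {0, 1}
            times = rec.truth_events[leg].times
            assert np.all(np.diff(times) > 0)
            types = rec.truth_events[leg].types
            assert all(a != b for a, b in zip(types, types[1:]))

    def test_legs_are_half_cycle_offset(self, short_subject):
        rec = short_subject
        hs_l = rec.truth_events["left"].of_type("HS")
        hs_r = rec.truth_events["right"].of_type("HS")
        # each right HS should fall near the midpoint between left HSs
        mids = (hs_l[:-1] + hs_l[1:]) / 2
        for m in mids[1:-1]:
            assert np.min(np.abs(hs_r - m)) < 120  # ms, ~10% of a stride

    def test_zero_heterogeneity_shares_parameters(self):
        base = GaitSimParams(duration_s=8, seed=3)
        recs = generate_population(3, base, heterogeneity=0.0, seed=11)
        assert len(recs) == 3
        # identical gait statistics: same stride timing structure
        fracs = [np.mean(r.basographic["left"] == 0) for r in recs]
        assert np.ptp(fracs) < 0.02

    def test_heterogeneity_jitters_burst_centers(self):
        base = GaitSimParams(duration_s=8, seed=3)
        center0 = default_muscle_profiles()["L_TA"][0].center
        recs, params = generate_population(
            5, base, heterogeneity=0.3, seed=7, return_params=True
        )
        assert len(recs) == 5
        centers = [p.muscle_profiles["L_TA"][0].center for p in params]
        diffs = [
            abs(a - b)
            for i, a in enumerate(centers)
            for b in centers[i + 1 :]
        ]
        assert all(d > 0 for d in diffs)
        # jitter must leave the base profiles untouched
        assert base.muscle_profiles["L_TA"][0].center == center0

    def test_bad_population_size_errors(self):
        with pytest.raises(ParameterError):
            generate_population(0, GaitSimParams(duration_s=8), 0.1, 1)
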