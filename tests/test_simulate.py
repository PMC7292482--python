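"""Tests of the synthetic waveform generator and preprocessing."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dfenet as df
from dfenet.simulate import PAD_LENGTH, _build_beat, _draw_beat_params


def noiseless_params(**kw):
    return df.SimParams(noise_sd=0.0, seed=kw.pop("seed", 0), **kw)


class TestSimulateComplex:
    def test_peak_is_global_maximum_without_noise(self):
        params = noiseless_params()
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = df.simulate_complex(params, rng)
            peak, notch, nadir = c.landmarks
            assert c.samples[peak] == pytest.approx(c.raw_samples.max())
            assert np.argmax(c.raw_samples) == peak

    def test_notch_is_local_minimum_without_noise(self):
        rng = np.random.default_rng(1)
        c = df.simulate_complex(noiseless_params(), rng)
        _, notch, _ = c.landmarks
        assert c.samples[notch] < c.samples[notch - 1]
        assert c.samples[notch] < c.samples[notch + 1]

    def test_diastolic_decay_strictly_decreasing(self):
        rng = np.random.default_rng(2)
        params = noiseless_params()
        p = _draw_beat_params(params, rng)
        built = None
        while built is None:
            built = _build_beat(p, params.fs)
            if built is None:
                p["hr"] = rng.uniform(*params.heart_rate_range)
        beat, (peak, notch, nadir) = built
        bump_end = notch + max(3, int(round(0.06 * len(beat))))
        tail = beat[bump_end: nadir + 1]
        assert np.all(np.diff(tail) < 0)

    def test_landmark_ordering_always_holds(self):
        params = df.SimParams(seed=3)
        rng = np.random.default_rng(3)
        for _ in range(200):
            c = df.simulate_complex(params, rng)
            peak, notch, nadir = c.landmarks
            assert 0 <= peak < notch < nadir < c.raw_length <= PAD_LENGTH

    def test_padding_fills_with_last_raw_value(self):
        rng = np.random.default_rng(4)
        c = df.simulate_complex(df.SimParams(seed=4), rng)
        pad = c.samples[c.raw_length:]
        assert np.all(pad == c.samples[c.raw_length - 1])

    def test_deterministic_under_seeding(self):
        params = df.SimParams(seed=5)
        c1 = df.simulate_complex(params, np.random.default_rng(42))
        c2 = df.simulate_complex(params, np.random.default_rng(42))
        np.testing.assert_array_equal(c1.samples, c2.samples)
        assert c1.landmarks == c2.landmarks

    def test_low_heart_rate_beats_are_resampled_to_fit(self):
        # 50 bpm implies 300 samples; rejection must keep all beats <= 250
        params = df.SimParams(heart_rate_range=(50.0, 62.0), seed=6)
        rng = np.random.default_rng(6)
        for _ in range(50):
            assert df.simulate_complex(params, rng).raw_length <= PAD_LENGTH


class TestSimulateCohort:
    def test_total_beat_count_within_range_bounds(self, cohort):
        assert 100 * 8 <= len(cohort) <= 100 * 25
        assert len(cohort.subjects) == 100

    def test_single_subject_cohort(self):
        ds = df.simulate_cohort(df.SimParams(seed=8), 1)
        assert len({c.subject_id for c in ds.complexes}) == 1

    def test_same_seed_gives_identical_cohort(self):
        a = df.simulate_cohort(df.SimParams(seed=9), 4)
        b = df.simulate_cohort(df.SimParams(seed=9), 4)
        assert len(a) == len(b)
        for ca, cb in zip(a.complexes, b.complexes):
            np.testing.assert_array_equal(ca.samples, cb.samples)
            assert ca.landmarks == cb.landmarks

    def test_within_subject_beats_more_similar_than_between(self):
        ds = df.simulate_cohort(df.SimParams(seed=10, noise_sd=0.0), 12)
        by_subject = {}
        for c in ds.complexes:
            by_subject.setdefault(c.subject_id, []).append(c.raw_samples.max())
        within = np.mean([np.std(v) for v in by_subject.values() if len(v) > 1])
        between = np.std([np.mean(v) for v in by_subject.values()])
        assert within < between

    def test_csv_round_trip(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        small_cohort.to_csv(path)
        back = df.SubjectDataset.from_csv(path)
        assert len(back) == len(small_cohort)
        for ca, cb in zip(small_cohort.complexes, back.complexes):
            np.testing.assert_allclose(ca.samples, cb.samples)
            assert ca.landmarks == cb.landmarks
            assert ca.subject_id == cb.subject_id

    def test_unlabeled_beats_encode_as_empty_fields(self, tmp_path):
        c = df.pad_complex(np.linspace(80, 120, 200))
        ds = df.SubjectDataset([c], ["s0"])
        buf = io.StringIO()
        ds.to_csv(buf)
        buf.seek(0)
        back = df.SubjectDataset.from_csv(buf)
        assert back.complexes[0].landmarks is None


class TestDistalPressure:
    def test_identity_when_factor_one(self):
        rng = np.random.default_rng(12)
        pa = df.simulate_complex(noiseless_params(seed=12), rng)
        pd = df.make_distal_pressure(pa, 1.0, 0.0, rng)
        np.testing.assert_allclose(pd.samples, pa.samples)

    def test_scaling_by_gradient_factor(self):
        rng = np.random.default_rng(13)
        pa = df.simulate_complex(noiseless_params(seed=13), rng)
        pd = df.make_distal_pressure(pa, 0.8, 0.0, rng)
        np.testing.assert_allclose(pd.raw_samples, 0.8 * pa.raw_samples)

    def test_noisy_ratio_statistics(self):
        # mean(Pd / Pa) ~ 0.8 with sd ~ noise_sd * mean(1/Pa) / sqrt(n)
        rng = np.random.default_rng(14)
        pa = df.simulate_complex(noiseless_params(seed=14), rng)
        pd = df.make_distal_pressure(pa, 0.8, 1.0, rng)
        ratio = pd.raw_samples / pa.raw_samples
        sd_mean = np.mean(1.0 / pa.raw_samples) / np.sqrt(pa.raw_length)
        assert abs(np.mean(ratio) - 0.8) < 3 * sd_mean

    def test_invalid_gradient_factor_rejected(self):
        rng = np.random.default_rng(15)
        pa = df.simulate_complex(noiseless_params(seed=15), rng)
        for bad in (0.0, -0.5, 1.2):
            with pytest.raises(ValueError):
                df.make_distal_pressure(pa, bad, 0.0, rng)

    def test_requires_landmarks(self):
        rng = np.random.default_rng(16)
        unlabeled = df.pad_complex(np.linspace(60, 100, 180))
        with pytest.raises(ValueError):
            df.make_distal_pressure(unlabeled, 0.8, 0.0, rng)


class TestExtractComplexes:
    def _beat(self, seed=20):
        rng = np.random.default_rng(seed)
        return df.simulate_complex(noiseless_params(seed=seed), rng)

    def test_concatenated_beats_split_at_construction_boundaries(self):
        beat = self._beat().raw_samples
        trace = np.concatenate([beat] * 5)
        segments = df.extract_complexes(trace, fs=250.0)
        assert len(segments) == 5
        # cut points within +/- 2 samples of the true boundaries
        lengths = [len(s) for s in segments]
        boundaries = np.cumsum(lengths)[:-1]
        true = np.arange(1, 5) * len(beat)
        assert np.all(np.abs(boundaries - true) <= 2)

    def test_single_beat_returns_single_segment(self):
        beat = self._beat(21).raw_samples
        segments = df.extract_complexes(beat, fs=250.0)
        assert len(segments) == 1

    def test_constant_trace_raises(self):
        with pytest.raises(ValueError, match="periodicity"):
            df.extract_complexes(np.full(1000, 80.0), fs=250.0)

    def test_round_trip_with_noise(self):
        rng = np.random.default_rng(22)
        beat = self._beat(22).raw_samples
        trace = np.concatenate([beat] * 4) + rng.normal(0, 0.5, 4 * len(beat))
        segments = df.extract_complexes(trace, fs=250.0)
        assert len(segments) == 4
        # each cut point may jitter by ~2 samples, so a segment bounded by
        # two jittered cuts can differ from the true length by up to 4
        for s in segments:
            assert abs(len(s) - len(beat)) <= 4


class TestPadComplex:
    def test_full_length_beat_unchanged(self):
        beat = np.linspace(60, 120, PAD_LENGTH)
        c = df.pad_complex(beat)
        np.testing.assert_array_equal(c.samples, beat)
        assert c.raw_length == PAD_LENGTH

    def test_short_beat_padded_with_last_value(self):
        c = df.pad_complex(np.array([10.0, 20.0, 30.0]))
        assert c.raw_length == 3
        np.testing.assert_array_equal(c.samples[:3], [10, 20, 30])
        np.testing.assert_array_equal(c.samples[3:], 30.0)

    def test_overlong_beat_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            df.pad_complex(np.zeros(PAD_LENGTH + 1))

    @settings(max_examples=25, deadline=None)
    @given(n=st.integers(min_value=1, max_value=PAD_LENGTH))
    def test_padding_conserves_raw_sum(self, n):
        rng = np.random.default_rng(n)
        beat = rng.uniform(40, 180, n)
        c = df.pad_complex(beat)
        assert np.sum(c.samples[:n]) == pytest.approx(np.sum(beat))


class TestJitterLabels:
    def test_ordering_survives_any_shift(self, small_cohort):
        from dfenet.simulate import jitter_labels
        rng = np.random.default_rng(0)
        jittered = jitter_labels(small_cohort, 5, rng)
        for c in jittered.complexes:
            peak, notch, nadir = c.landmarks
            assert 0 <= peak < notch < nadir < c.raw_length

    def test_shifts_bounded_by_k(self, small_cohort):
        from dfenet.simulate import jitter_labels
        rng = np.random.default_rng(1)
        jittered = jitter_labels(small_cohort, 3, rng)
        for before, after in zip(small_cohort.complexes, jittered.complexes):
            deltas = np.abs(np.array(after.landmarks) - np.array(before.landmarks))
            assert np.all(deltas <= 3)

    def test_zero_shift_is_identity(self, small_cohort):
        from dfenet.simulate import jitter_labels
        rng = np.random.default_rng(2)
        jittered = jitter_labels(small_cohort, 0, rng)
        for before, after in zip(small_cohort.complexes, jittered.complexes):
            assert before.landmarks == after.landmarks


class TestWaveformComplexInvariants:
    def test_bad_landmark_order_rejected(self):
        samples = np.zeros(PAD_LENGTH)
        with pytest.raises(ValueError):
            df.WaveformComplex(samples, raw_length=200, landmarks=(50, 40, 100))

    def test_landmark_beyond_raw_length_rejected(self):
        samples = np.zeros(PAD_LENGTH)
        with pytest.raises(ValueError):
            df.WaveformComplex(samples, raw_length=100, landmarks=(10, 50, 150))
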