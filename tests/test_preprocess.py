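"""Preprocessing: artifact detection, filtering, averaging, DIFF."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import tscs_tune as tt
from tscs_tune.cohort import ACC_RATE, EMG_RATE, MUSCLES, twitch_waveform
from tscs_tune.preprocess import (N_ACC_CROP, N_EMG_CROP,
                                  running_median_highpass)

from conftest import make_model


def naive_running_median(x, kernel=31):
    """Brute-force sliding median with symmetric edge padding."""
    pad = kernel // 2
    xp = np.pad(x, pad, mode="symmetric")
    return np.array([np.median(xp[i:i + kernel]) for i in range(x.size)])


class TestArtifactDetection:
    def test_double_pulse_two_detections_at_injected_times(self):
        m = make_model()
        emg, _ = tt.simulate_event_pair(m, 15.0, "double", 0, noise=False)
        det = tt.detect_stimulation_artifacts(emg)
        assert det.size == 2
        # pulses injected at 0.1 s and 0.15 s; tolerance one sample
        np.testing.assert_allclose(det, [0.1, 0.15], atol=1.5 / EMG_RATE)

    def test_single_pulse_one_detection(self):
        m = make_model(emg_noise_sd=3.0)
        emg, _ = tt.simulate_event_pair(m, 15.0, "single", 3)
        det = tt.detect_stimulation_artifacts(emg)
        assert det.size == 1
        assert abs(det[0] - 0.1) <= 1.5 / EMG_RATE

    def test_all_zero_signal_empty(self):
        assert tt.detect_stimulation_artifacts(np.zeros(1000)).size == 0

    def test_refractory_merges_burst(self):
        x = np.zeros(500)
        x[100] = 1000.0  # one spike excites several d2 samples
        det = tt.detect_stimulation_artifacts(x, dd_threshold=10.0)
        assert det.size == 1


class TestCropAndFilterEmg:
    def test_crop_length_and_constant_removed(self):
        x = np.full(1000, 123.0)
        crop = tt.crop_and_filter_emg(x, 0.5)
        assert crop.samples.size == N_EMG_CROP
        np.testing.assert_allclose(crop.samples, 0.0, atol=1e-6)

    def test_50hz_notch_steady_state_attenuation(self):
        """The anti-hum notch attenuates a sustained 50 Hz tone by well over
        20 dB once filtfilt edge transients have decayed."""
        from scipy import signal

        t = np.arange(2000) / EMG_RATE
        x = np.sin(2 * np.pi * 50.0 * t)
        b, a = signal.iirnotch(50.0, 30.0, fs=EMG_RATE)
        y = signal.filtfilt(b, a, x)
        mid = slice(500, 1500)
        atten_db = 20 * np.log10(np.sqrt(np.mean(x[mid] ** 2))
                                 / np.sqrt(np.mean(y[mid] ** 2)))
        assert atten_db >= 20.0

    def test_50hz_tone_attenuated_in_crop(self):
        """Through the full crop-and-filter chain (410 ms window, edge
        transients included) a 50 Hz tone still loses most of its power."""
        t = np.arange(1000) / EMG_RATE
        x = np.sin(2 * np.pi * 50.0 * t)
        crop = tt.crop_and_filter_emg(x, 0.5)
        rms_in = np.sqrt(np.mean(x[490:900] ** 2))
        rms_out = np.sqrt(np.mean(crop.samples**2))
        assert 20 * np.log10(rms_in / rms_out) >= 8.0

    def test_drift_removed_spike_preserved(self):
        t = np.arange(1000)
        x = 0.05 * t  # slow drift
        x[500:505] += 200.0  # 5-sample spike
        y = running_median_highpass(x, 31)
        np.testing.assert_allclose(naive_running_median(x, 31), x - y)
        assert np.ptp(y[:400]) < 2.0  # drift gone
        assert y[500:505].max() >= 0.8 * 200.0

    def test_out_of_bounds_crop_raises(self):
        with pytest.raises(ValueError):
            tt.crop_and_filter_emg(np.zeros(300), 0.005)

    @given(hnp.arrays(np.float64, 256,
                      elements=st.floats(-1e3, 1e3, allow_nan=False)))
    def test_running_median_matches_bruteforce(self, x):
        """The running-median high-pass equals signal minus the naive
        sliding median, sample for sample."""
        y = running_median_highpass(x, 31)
        np.testing.assert_array_equal(y, x - naive_running_median(x, 31))


class TestPreprocessAcc:
    def test_gravity_offset_removed(self):
        x = np.full(500, 9.81)
        crop = tt.preprocess_acc(x, 0.5)
        assert crop.samples.size == N_ACC_CROP
        np.testing.assert_allclose(crop.samples, 0.0, atol=1e-12)

    def test_zero_baseline_unchanged(self):
        x = np.zeros(500)
        x[260:270] = 1.5  # response after the artifact time
        crop = tt.preprocess_acc(x, 0.5)
        np.testing.assert_array_equal(crop.samples,
                                      x[245:450])

    def test_time_shift_equivariance(self):
        """Shifting sweep and artifact time together leaves the crop
        unchanged."""
        rng = np.random.default_rng(0)
        base = rng.normal(size=400)
        shifted = np.concatenate([np.zeros(50), base])
        a = tt.preprocess_acc(base, 0.3)
        b = tt.preprocess_acc(shifted, 0.3 + 50 / ACC_RATE)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestSimilarityAverage:
    def test_identical_sweeps_average_exactly(self):
        x = np.random.default_rng(0).normal(size=100)
        avg, kept = tt.similarity_average([x, x.copy(), x.copy()])
        assert kept == [0, 1, 2]
        np.testing.assert_array_equal(avg, x)

    def test_outlier_dropped(self):
        rng = np.random.default_rng(1)
        x = np.sin(np.linspace(0, 6, 200))
        noise = rng.normal(size=200)
        avg, kept = tt.similarity_average([x, x + 1e-8, noise])
        assert kept == [0, 1]
        np.testing.assert_allclose(avg, x, atol=1e-7)
        # brute-force R^2 confirms the outlier is dissimilar
        r = np.corrcoef(x, noise)[0, 1]
        assert r * r < 0.8

    def test_mutually_dissimilar_faulty(self):
        rng = np.random.default_rng(2)
        reps = [rng.normal(size=150) for _ in range(3)]
        avg, kept = tt.similarity_average(reps)
        assert avg is None and kept == []

    def test_low_amplitude_floor_links_quiet_sweeps(self):
        rng = np.random.default_rng(3)
        reps = [rng.normal(0, 0.01, 150) for _ in range(3)]
        avg, kept = tt.similarity_average(reps, low_amplitude_rms=0.05)
        assert kept == [0, 1, 2]
        np.testing.assert_allclose(avg, np.mean(reps, axis=0))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tt.similarity_average([np.zeros(5), np.zeros(6)])


class TestComputeDiff:
    def test_equal_inputs_zero(self):
        x = np.ones(10)
        np.testing.assert_array_equal(tt.compute_diff(x, x), np.zeros(10))

    def test_zero_single_identity(self):
        d = np.arange(10.0)
        np.testing.assert_array_equal(tt.compute_diff(d, np.zeros(10)), d)

    @given(hnp.arrays(np.float64, 32, elements=st.floats(-1e3, 1e3)),
           hnp.arrays(np.float64, 32, elements=st.floats(-1e3, 1e3)),
           hnp.arrays(np.float64, 32, elements=st.floats(-1e3, 1e3)))
    def test_common_signal_cancels(self, a, b, c):
        """compute_diff(a + c, b + c) == compute_diff(a, b)."""
        np.testing.assert_allclose(tt.compute_diff(a + c, b + c),
                                   tt.compute_diff(a, b), atol=1e-6)

    def test_diff_recovers_second_twitch_template(self):
        """Noise-free with linear summation: DIFF equals the generator's
        second-twitch template."""
        m = make_model(summation_gain=1.0)
        current = 18.0
        _, acc_d = tt.simulate_event_pair(m, current, "double", 0, noise=False)
        _, acc_s = tt.simulate_event_pair(m, current, "single", 0, noise=False)
        t_art = 0.1
        crop_d = tt.preprocess_acc(acc_d, t_art).samples
        crop_s = tt.preprocess_acc(acc_s, t_art).samples
        diff = tt.compute_diff(crop_d, crop_s)
        r, d = m.recruitment(current)
        amp2 = (m.twitch_amplitude * (r + d)
                * (1 - m.effective_suppression(current) / 100.0))
        tw = twitch_waveform(m)
        template = np.zeros_like(diff)
        # second pulse is 50 ms after the first; crop starts at -10 ms
        i0 = int(round((50 + 10) / 1000 * ACC_RATE))
        seg = template[i0:i0 + tw.size]
        seg += amp2 * tw[: seg.size]
        assert np.sqrt(np.mean((diff - template) ** 2)) < 1e-9


@pytest.fixture(scope="module")
def session():
    meta = tt.SubjectMeta("S1", 30.0, 0, 180.0, 22.0, "healthy")
    models = {m: make_model(
        muscle_id=m, latency_ms=18.0 if m.startswith("TS") else 8.0)
        for m in MUSCLES}
    proto = tt.StimulationProtocol(max_current=20.0)
    return tt.generate_session(meta, proto, models, 0.0, seed=1)


class TestPreprocessSession:
    def test_clean_session_nothing_excluded(self, session):
        events, report = tt.preprocess_session(session)
        assert report["fraction_excluded"] == 0.0
        assert all(ev.valid for ev in events)

    def test_event_count_is_muscles_times_currents(self, session):
        events, _ = tt.preprocess_session(session)
        assert len(events) == 4 * session.protocol.currents().size

    def test_diff_consistency_when_valid(self, session):
        events, _ = tt.preprocess_session(session)
        for ev in events:
            np.testing.assert_allclose(
                ev.acc_diff, ev.acc_double_avg - ev.acc_single_avg)

    def test_corrupted_triplet_excluded(self, session):
        """Replacing one repetition triplet with independent noise excludes
        exactly that event."""
        corrupted = tt.SessionRecording(
            meta=session.meta, position=session.position, day=session.day,
            protocol=session.protocol, emg=session.emg.copy(),
            acc_z=session.acc_z.copy(), events=session.events,
            ground_truth=session.ground_truth)
        rng = np.random.default_rng(9)
        log = session.events
        first_current = session.protocol.currents()[2]
        sel = log[(np.isclose(log.current_ma, first_current))
                  & (log.pulse_type == "double")]
        for _, row in sel.iterrows():
            i = int(row.time_s * 1000)
            corrupted.emg[0, i - 100:i + 500] = rng.normal(0, 30.0, 600)
        events, report = tt.preprocess_session(corrupted)
        bad = [ev for ev in events if not ev.valid]
        assert len(bad) == 1
        assert bad[0].muscle == "Q_left"
        assert bad[0].current == first_current
        assert bad[0].invalid_reason == "similarity_fail"
        assert report["fraction_excluded"] == pytest.approx(1 / len(events))
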