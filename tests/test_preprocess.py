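"""Cleaning-chain checks against closed-form filter responses and the
generators' ground truth."""

import numpy as np
import pytest
from scipy import signal as sps

from physiotrust import preprocess as pp
from physiotrust.synth import signals as sig


def _tone(freq, fs, dur=45.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t), t


class TestEcgFilter:
    def test_60hz_mains_removed(self):
        x, _ = _tone(60.0, 500)
        y = pp.filter_ecg(x, 500)
        assert np.max(np.abs(y[1000:-1000])) < 0.01  # < 1% of input amplitude

    def test_dc_removed_by_highpass(self):
        y = pp.filter_ecg(np.full(5000, 3.3), 500)
        assert np.max(np.abs(y[500:-500])) < 1e-3

    def test_zero_phase_no_peak_shift(self):
        x, _ = _tone(10.0, 500)
        y = pp.filter_ecg(x, 500)
        lag = np.argmax(np.correlate(y[2000:-2000], x[2000:-2000], "full"))
        assert lag == len(x[2000:-2000]) - 1  # zero-lag peak

    def test_length_preserved_and_validation(self):
        x, _ = _tone(5.0, 500, dur=10)
        assert pp.filter_ecg(x, 500).shape == x.shape
        with pytest.raises(ValueError):
            pp.filter_ecg(x, 150)
        with pytest.raises(ValueError):
            pp.filter_ecg(np.array([1.0, np.nan]), 500)


class TestRPeaks:
    def test_against_generator_truth(self):
        x, tr = sig.generate_ecg(45, mean_hr_bpm=60, hrv_sd_ms=30, fs=500, seed=5)
        peaks, ok = pp.detect_r_peaks(pp.filter_ecg(x, 500), 500)
        assert ok
        assert abs(len(peaks) - len(tr["r_peaks"])) <= 1
        err = np.abs(peaks[:, None] - tr["r_peaks"][None, :]).min(axis=1)
        assert np.mean(err) < 0.010  # < 10 ms

    def test_two_rates_concatenated(self):
        x1, t1 = sig.generate_ecg(30, mean_hr_bpm=60, hrv_sd_ms=0, fs=500, seed=1)
        x2, t2 = sig.generate_ecg(30, mean_hr_bpm=90, hrv_sd_ms=0, fs=500, seed=2)
        x = np.concatenate([x1, x2])
        peaks, _ = pp.detect_r_peaks(pp.filter_ecg(x, 500), 500)
        first, second = peaks[peaks < 30.0], peaks[peaks >= 30.0]
        assert abs(len(first) - len(t1["r_peaks"])) <= 1
        assert abs(len(second) - len(t2["r_peaks"])) <= 1

    def test_flat_signal_flagged_not_raised(self):
        peaks, ok = pp.detect_r_peaks(np.zeros(5000), 500)
        assert peaks.size == 0 and not ok

    def test_strictly_increasing_with_refractory(self):
        x, _ = sig.generate_ecg(60, mean_hr_bpm=120, hrv_sd_ms=60, fs=500, seed=9)
        peaks, _ = pp.detect_r_peaks(pp.filter_ecg(x, 500), 500)
        assert np.all(np.diff(peaks) >= 0.2)


class TestEdaCleaning:
    def test_constant_preserved(self):
        y, ok = pp.clean_eda(np.full(45 * 32, 5.0), 32)
        assert ok and np.allclose(y, 5.0, atol=1e-6)
        assert y.size == 450  # resampled to 10 Hz

    def test_out_of_range_spike_interpolated(self):
        x = np.full(45 * 32, 5.0)
        x[700] = 80.0
        y, ok = pp.clean_eda(x, 32)
        assert ok and y.max() < 41.0

    def test_mostly_bad_epoch_flagged(self):
        x = np.full(45 * 32, 0.2)  # below the 1 µS floor
        _, ok = pp.clean_eda(x, 32)
        assert not ok


class TestEdaDecomposition:
    def test_constant_input(self):
        tonic, phasic, events = pp.decompose_eda(np.full(450, 7.0))
        assert np.allclose(tonic, 7.0, atol=0.01)
        assert np.allclose(phasic, 0.0, atol=0.01)
        assert events == []

    def test_reconstruction_is_exact(self):
        x, _ = sig.generate_eda(45, seed=3)
        c10, _ = pp.clean_eda(x, 32)
        tonic, phasic, _ = pp.decompose_eda(c10)
        rms = np.sqrt(np.mean((c10 - tonic - phasic) ** 2))
        assert rms <= 0.02 * np.std(c10)

    def test_single_planted_scr_recovered(self):
        x, tr = sig.generate_eda(
            45, scr_rate_per_min=0, scr_amp_uS=0.5, amp_cv=0.0,
            noise_uS=0.002, seed=4, scr_times=np.array([15.0]),
        )
        c10, _ = pp.clean_eda(x, 32)
        _, _, events = pp.decompose_eda(c10)
        assert len(events) == 1
        assert abs(events[0].amplitude_uS - 0.5) < 0.075  # within 15%
        assert abs(events[0].onset_s - 15.0) < 2.0

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            pp.decompose_eda(np.full(100, 5.0))


class TestRespFilter:
    def test_passband_tone_preserved(self):
        x, _ = _tone(0.25, 32, dur=240)  # 15 breaths/min
        y = pp.filter_resp(x, 32)
        core = slice(int(80 * 32), -int(80 * 32))  # skip slow-corner transients
        assert abs(np.max(np.abs(y[core])) - 1.0) < 0.05

    def test_slow_drift_attenuated(self):
        x, _ = _tone(0.01, 32, dur=400)
        y = pp.filter_resp(x, 32)
        assert np.max(np.abs(y[3000:-3000])) < 0.1  # > 90% attenuation

    def test_breath_detection_rate(self):
        x, tr = sig.generate_resp(90, rate_bpm=15, seed=0)
        cycles, ok = pp.detect_breaths(pp.filter_resp(x, 32), 32)
        assert ok
        rate = 60.0 / np.mean(np.diff(cycles))
        assert abs(rate - 15.0) < 0.5

    def test_flat_input_flagged(self):
        cycles, ok = pp.detect_breaths(np.zeros(1000), 32)
        assert cycles.size == 0 and not ok


class TestEegPreprocess:
    def test_blink_free_reconstruction_close_to_filtered(self):
        x, _ = sig.generate_eeg(20, blink_rate_per_min=0, seed=0)
        filt, _ = pp.preprocess_eeg(x, 250, run_ica=False)
        clean, info = pp.preprocess_eeg(x, 250, seed=0)
        assert info["ica_ok"]
        assert info["rejected"] == []
        assert np.allclose(clean, filt, atol=1e-6)

    def test_blink_artifact_power_halved_frontally(self):
        x, _ = sig.generate_eeg(45, blink_rate_per_min=15, seed=1)
        filt, _ = pp.preprocess_eeg(x, 250, run_ica=False)
        clean, info = pp.preprocess_eeg(x, 250, seed=0)

        def low_power(sig1):
            f, P = sps.welch(sig1, fs=250, nperseg=512)
            m = (f >= 0.5) & (f <= 3.0)  # blink transients live here
            return np.trapezoid(P[m], f[m])

        assert info["rejected"]
        assert low_power(clean[0]) < 0.5 * low_power(filt[0])

    def test_60hz_attenuated_by_bandpass_edge(self):
        x, t = _tone(60.0, 250)
        data = np.tile(x, (19, 1))
        y, _ = pp.preprocess_eeg(data, 250, run_ica=False)
        assert np.max(np.abs(y[0][2000:-2000])) < 0.5  # > 50% amplitude cut

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            pp.preprocess_eeg(np.zeros((7, 1000)), 250)


class TestFnirsFilter:
    def test_linear_ramp_removed(self):
        t = np.arange(450) / 10.0
        ramp = np.tile(t, (20, 1))
        o, r = pp.filter_fnirs(ramp, ramp, 10.0)
        # detrended output: residual slope < 5% of input slope
        slope = np.polyfit(t, o[0], 1)[0]
        assert abs(slope) < 0.05

    def test_cardiac_ripple_attenuated(self):
        x, _ = _tone(1.0, 10.0, dur=400)
        d = np.tile(x, (20, 1))
        o, _ = pp.filter_fnirs(d, d, 10.0)
        core = slice(int(150 * 10), -int(150 * 10))
        assert np.max(np.abs(o[0][core])) < 0.1

    def test_hrf_band_tone_preserved(self):
        x, _ = _tone(0.1, 10.0, dur=400)
        d = np.tile(x, (20, 1))
        o, _ = pp.filter_fnirs(d, d, 10.0)
        core = slice(int(150 * 10), -int(150 * 10))
        assert abs(np.max(np.abs(o[0][core])) - 1.0) < 0.1

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            pp.filter_fnirs(np.zeros((20, 50)), np.zeros((20, 50)), 0.8)
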