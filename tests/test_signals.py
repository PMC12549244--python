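"""Generator oracles: each synthetic stream is checked against its own
returned ground truth or against closed-form expectations."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy.stats import chisquare, poisson

from physiotrust.synth import signals as sig


class TestEcg:
    def test_uniform_rr_at_60_bpm(self):
        x, tr = sig.generate_ecg(45, mean_hr_bpm=60, hrv_sd_ms=0, fs=500, seed=0)
        assert abs(len(tr["r_peaks"]) - 45) <= 1
        assert np.allclose(np.diff(tr["r_peaks"]), 1.0, atol=1e-9)

    def test_rr_variability_matches_requested_sd(self):
        # sample SD of the generator's own RR draws, n >= 200 beats
        x, tr = sig.generate_ecg(240, mean_hr_bpm=72, hrv_sd_ms=50, fs=250, seed=1)
        rr = tr["rr_intervals"] * 1000.0
        assert rr.size >= 200
        assert abs(np.std(rr, ddof=1) - 50.0) < 10.0  # within 20%

    def test_mains_contaminant_visible_in_spectrum(self):
        x, _ = sig.generate_ecg(45, fs=500, seed=2, mains_amp=0.1)
        f, P = sps.welch(x, fs=500, nperseg=4096)
        band = P[(f > 58) & (f < 62)].max()
        neighbor = P[(f > 50) & (f < 55)].max()
        assert band > 10 * neighbor

    @pytest.mark.parametrize("hr", [20.0, 250.0])
    def test_out_of_range_heart_rate_rejected(self, hr):
        with pytest.raises(ValueError):
            sig.generate_ecg(45, mean_hr_bpm=hr)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            sig.generate_ecg(0.5, mean_hr_bpm=40)


class TestEda:
    def test_zero_rate_gives_pure_tonic(self):
        x, tr = sig.generate_eda(45, scr_rate_per_min=0, noise_uS=0, seed=0)
        assert np.allclose(x, tr["tonic"])

    def test_planted_scr_peak_matches_bateman_analytics(self):
        # one SCR of 0.5 µS: the kernel is normalized to unit peak, so
        # max(signal - tonic) must sit within 10% of 0.5
        x, tr = sig.generate_eda(
            45, scr_rate_per_min=0, scr_amp_uS=0.5, amp_cv=0.0,
            noise_uS=0.0, seed=1, scr_times=np.array([10.0]),
        )
        assert abs(np.max(x - tr["tonic"]) - 0.5) < 0.05

    def test_poisson_event_counts_across_seeds(self):
        # rate 4/min over 45 s -> Poisson(3); chi-square over 500 seeds
        counts = [
            len(sig.generate_eda(45, scr_rate_per_min=4, seed=s)[1]["scr_onsets"])
            for s in range(500)
        ]
        edges = list(range(7))
        obs = np.array([np.sum(np.array(counts) == k) for k in edges]
                       + [np.sum(np.array(counts) > edges[-1])])
        pmf = [poisson.pmf(k, 3.0) for k in edges]
        pmf.append(1.0 - sum(pmf))
        exp = 500 * np.array(pmf)
        stat, p = chisquare(obs, exp)
        assert p > 0.01

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            sig.generate_eda(45, tonic_level_uS=0.5)
        with pytest.raises(ValueError):
            sig.generate_eda(45, scr_rate_per_min=-1)


class TestResp:
    def test_breath_count_matches_rate(self):
        x, tr = sig.generate_resp(45, rate_bpm=15, seed=0)
        assert 10 <= len(tr["cycle_times"]) <= 12  # ~11.25 cycles fit

    def test_out_of_range_rate_rejected(self):
        with pytest.raises(ValueError):
            sig.generate_resp(45, rate_bpm=200)


class TestEeg:
    def test_shape_and_labels(self):
        x, tr = sig.generate_eeg(45, fs=250, seed=0)
        assert x.shape == (19, 11250)
        assert tr["channels"] == sig.EEG_CHANNELS

    def test_alpha_dominance_when_alpha_target_10x(self):
        targets = {b: 2.0 for b in sig.EEG_BANDS}
        targets["alpha"] = 20.0
        x, _ = sig.generate_eeg(45, band_power_targets=targets,
                                blink_rate_per_min=0, seed=1)
        f, P = sps.welch(x, fs=250, nperseg=500, axis=-1)
        for c in range(19):
            powers = {}
            for band, (lo, hi) in sig.EEG_BANDS.items():
                m = (f >= lo) & (f <= hi)
                powers[band] = np.trapezoid(P[c][m], f[m])
            assert max(powers, key=powers.get) == "alpha"

    def test_blink_free_symmetric_artifact_power(self):
        x, tr = sig.generate_eeg(45, blink_rate_per_min=0, seed=2)
        assert tr["blink_times"].size == 0

    def test_channel_override_required(self):
        with pytest.raises(ValueError):
            sig.generate_eeg(10, n_channels=8)
        x, _ = sig.generate_eeg(10, n_channels=8, allow_channel_override=True, seed=0)
        assert x.shape[0] == 8


class TestFnirs:
    def test_planted_hrf_time_to_peak(self):
        (hbo, _), tr = sig.generate_fnirs(
            45, event_times=[0.0], time_to_peak_s=6.0,
            drift_amp=0.0, cardiac_amp=0.0, noise=0.0, seed=0,
        )
        assert tr["time_to_peak_s"] == 6.0
        assert abs(np.argmax(hbo[0]) / 10.0 - 6.0) < 0.5

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            sig.generate_fnirs(45, fs=1.0)


class TestEye:
    def test_bundle_structure(self):
        b, tr = sig.generate_eye(45, seed=0)
        assert b["pupil"].shape == (45 * 120,)
        assert set(b["fixations"]) == {"onset", "duration", "aoi"}
        assert np.all(np.diff(b["fixations"]["onset"]) > 0)

    def test_out_of_range_pupil_rejected(self):
        with pytest.raises(ValueError):
            sig.generate_eye(45, pupil_mean_mm=0.5)


def test_generators_are_deterministic_under_seed():
    for maker in (
        lambda s: sig.generate_ecg(10, seed=s)[0],
        lambda s: sig.generate_eda(45, seed=s)[0],
        lambda s: sig.generate_resp(10, seed=s)[0],
        lambda s: sig.generate_eeg(5, seed=s)[0],
        lambda s: sig.generate_fnirs(30, seed=s)[0][0],
        lambda s: sig.generate_eye(10, seed=s)[0]["pupil"],
    ):
        assert np.array_equal(maker(123), maker(123))
        assert not np.array_equal(maker(123), maker(124))
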