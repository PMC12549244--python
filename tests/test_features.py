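"""Feature-extractor checks: frozen category counts, hand-computed values,
and generator-truth comparisons."""

import numpy as np
import pytest
from scipy import signal as sps

from physiotrust import preprocess as pp
from physiotrust.features import (
    apply_feature_version,
    extract_ecg_features,
    extract_eda_features,
    extract_eeg_features,
    extract_embedded,
    extract_eye_features,
    extract_fnirs_features,
    extract_resp_features,
)
from physiotrust.features.dictionary import (
    CATEGORY_COUNTS,
    CATEGORY_FEATURES,
    FEATURE_DICTIONARY,
    N_VERSIONED_FEATURES,
)
from physiotrust.synth import signals as sig
from physiotrust.synth.embedded import generate_embedded


def test_dictionary_category_counts_match_contract():
    assert CATEGORY_COUNTS == {
        "ecg": 28, "eda": 63, "rsp": 28, "eeg": 125,
        "fnirs": 360, "eye": 37, "embedded": 16, "background": 25,
    }
    for cat, names in CATEGORY_FEATURES.items():
        assert len(names) == CATEGORY_COUNTS[cat]
        assert len(set(names)) == len(names)


def test_versioned_expansion_count():
    assert N_VERSIONED_FEATURES == 156 * 8 + 125 + 360 + 16 + 25 == 1774
    names = FEATURE_DICTIONARY.versioned_names()
    assert len(set(names)) == 1774
    # EEG only version 4, fNIRS only version 1
    assert "eeg_Pz_alpha__v4" in names and "eeg_Pz_alpha__v1" not in names
    assert "fnirs_ch01_hbo_max__v1" in names and "fnirs_ch01_hbo_max__v4" not in names
    assert "emb_session" in names and "bg_age" in names


class TestEcgFeatures:
    def test_uniform_rr(self):
        peaks = np.arange(0, 45, 1.0)  # 1,000-ms RR
        f = extract_ecg_features(peaks, 45.0)
        assert len(f) == 28
        assert f["ecg_rr_mean"] == pytest.approx(1000.0)
        assert f["ecg_sdnn"] == pytest.approx(0.0, abs=1e-9)
        assert f["ecg_rmssd"] == pytest.approx(0.0, abs=1e-9)
        assert f["ecg_hr_mean"] == pytest.approx(60.0)

    def test_rmssd_hand_computed(self):
        # RR = 800, 850, 900 ms -> successive diffs 50, 50 -> RMSSD = 50
        peaks = np.array([0.0, 0.8, 1.65, 2.55])
        f = extract_ecg_features(peaks, 45.0)
        assert f["ecg_rmssd"] == pytest.approx(50.0, abs=1e-9)

    def test_too_few_peaks_all_missing(self):
        f = extract_ecg_features(np.array([0.0, 1.0]), 45.0)
        assert len(f) == 28 and all(np.isnan(v) for v in f.values())


class TestEdaFeatures:
    def test_constant_no_scr(self):
        x = np.full(450, 5.0)
        f = extract_eda_features(x, x, np.zeros(450), [])
        assert len(f) == 63
        assert f["eda_scl_mean"] == pytest.approx(5.0)
        assert f["eda_scl_sd"] == pytest.approx(0.0)
        assert f["eda_scr_count"] == 0.0 and f["eda_scr_rate"] == 0.0
        assert np.isnan(f["eda_scr_amp_mean"])

    def test_two_planted_scrs_amplitude_sum(self):
        x, _ = sig.generate_eda(
            45, scr_rate_per_min=0, amp_cv=0.0, noise_uS=0.002, seed=0,
            scr_times=np.array([8.0, 25.0]), scr_amp_uS=0.4,
        )
        # plant 0.3 and 0.5 by scaling: regenerate with explicit amps via two calls
        x1, t1 = sig.generate_eda(45, scr_rate_per_min=0, amp_cv=0.0, noise_uS=0.0,
                                  seed=0, scr_times=np.array([8.0]), scr_amp_uS=0.3)
        x2, t2 = sig.generate_eda(45, scr_rate_per_min=0, amp_cv=0.0, noise_uS=0.0,
                                  seed=1, scr_times=np.array([25.0]), scr_amp_uS=0.5)
        x = x1 + (x2 - t2["tonic"])  # tonic once, both SCRs
        c10, _ = pp.clean_eda(x, 32)
        tonic, phasic, ev = pp.decompose_eda(c10)
        f = extract_eda_features(c10, tonic, phasic, ev)
        assert f["eda_scr_count"] == 2.0
        assert f["eda_scr_amp_sum"] == pytest.approx(0.8, rel=0.15)


class TestRespFeatures:
    def test_rate_from_sinusoid(self):
        x, tr = sig.generate_resp(45, rate_bpm=15, seed=0)
        filt = pp.filter_resp(x, 32)
        cycles, _ = pp.detect_breaths(filt, 32)
        f = extract_resp_features(filt, cycles, 32)
        assert len(f) == 28
        assert abs(f["rsp_rate"] - 15.0) < 0.5

    def test_symmetric_sinusoid_ie_ratio(self):
        t = np.arange(45 * 32) / 32.0
        x = np.sin(2 * np.pi * 0.25 * t)
        cycles, _ = pp.detect_breaths(x, 32)
        f = extract_resp_features(x, cycles, 32)
        assert f["rsp_ie_ratio"] == pytest.approx(1.0, abs=0.1)

    def test_too_few_cycles_missing(self):
        f = extract_resp_features(np.zeros(100), np.array([1.0]), 32)
        assert all(np.isnan(v) for v in f.values())


class TestEegFeatures:
    def test_pure_tone_alpha_dominant_dft_oracle(self):
        fs = 250.0
        t = np.arange(int(45 * fs)) / fs
        data = 0.05 * np.random.default_rng(0).standard_normal((19, t.size))
        data[4] += 10.0 * np.sin(2 * np.pi * 10.0 * t)  # 10 Hz on Fz
        f = extract_eeg_features(data, fs)
        assert len(f) == 125
        alpha = f["eeg_Fz_alpha"]
        for band in ("delta", "theta", "beta", "gamma"):
            assert alpha > 10 * f[f"eeg_Fz_{band}"]
        # direct DFT oracle: tone power ~ A^2/2
        spec = np.abs(np.fft.rfft(data[4])) ** 2 / (t.size * fs)
        freqs = np.fft.rfftfreq(t.size, 1 / fs)
        m = (freqs >= 8) & (freqs <= 13)
        oracle = 2 * np.sum(spec[m]) * (freqs[1] - freqs[0]) * t.size / t.size
        assert alpha == pytest.approx(10.0**2 / 2, rel=0.1)
        assert oracle == pytest.approx(alpha, rel=0.15)

    def test_identical_channels_region_means_equal(self):
        rng = np.random.default_rng(1)
        row = rng.standard_normal(2500)
        data = np.tile(row, (19, 1))
        f = extract_eeg_features(data, 250.0)
        for band in ("alpha", "beta"):
            ref = f[f"eeg_Fp1_{band}"]
            for region in ("prefrontal", "central", "parietal", "occipital", "temporal", "whole"):
                assert f[f"eeg_{region}_{band}"] == pytest.approx(ref, rel=1e-9)


class TestFnirsFeatures:
    def test_all_zero_input(self):
        z = np.zeros((20, 450))
        f = extract_fnirs_features(z, z, 10.0)
        assert len(f) == 360
        assert f["fnirs_ch01_hbo_mean"] == 0.0
        assert f["fnirs_ch01_hbo_var"] == 0.0
        assert f["fnirs_ch01_hbo_auc"] == 0.0
        assert f["fnirs_ch01_hbo_slope"] == pytest.approx(0.0, abs=1e-12)

    def test_planted_hrf_time_to_max(self):
        (hbo, hbr), _ = sig.generate_fnirs(
            45, event_times=[0.0], time_to_peak_s=6.0, drift_amp=0.0,
            cardiac_amp=0.0, noise=0.0, seed=0,
        )
        f = extract_fnirs_features(hbo, hbr, 10.0)
        assert abs(f["fnirs_ch01_hbo_ttmax"] - 6.0) < 0.5


class TestEyeFeatures:
    def test_constant_pupil_no_events(self):
        bundle = {
            "pupil": np.full(45 * 120, 3.0),
            "blinks": {"onset": np.array([]), "duration": np.array([])},
            "fixations": {"onset": np.array([]), "duration": np.array([]),
                          "aoi": np.array([], dtype=int)},
            "saccades": {"onset": np.array([]), "amplitude_deg": np.array([])},
        }
        f = extract_eye_features(bundle, 120.0, 45.0)
        assert len(f) == 37
        assert f["eye_pupil_sd"] == pytest.approx(0.0)
        assert f["eye_blink_count"] == 0.0
        assert np.isnan(f["eye_aoi_trans_entropy"])  # no fixation pairs

    def test_single_aoi_dwell_and_zero_entropy(self):
        bundle = {
            "pupil": np.full(1000, 3.0),
            "blinks": {"onset": np.array([]), "duration": np.array([])},
            "fixations": {
                "onset": np.array([0.0, 1.0, 2.0]),
                "duration": np.array([0.5, 0.6, 0.7]),
                "aoi": np.array([2, 2, 2]),
            },
            "saccades": {"onset": np.array([0.8, 1.9]),
                         "amplitude_deg": np.array([5.0, 6.0])},
        }
        f = extract_eye_features(bundle, 120.0, 45.0)
        assert f["eye_dwell_aoi3"] == pytest.approx(1.8)
        assert f["eye_aoi_trans_count"] == 0.0
        assert f["eye_aoi_trans_entropy"] == pytest.approx(0.0)


class TestEmbedded:
    def test_percent_reviewed_hand_example(self):
        rec = {
            "session": 1, "trial": 2, "epoch": 3, "explainability": "high",
            "n_satellites": 10, "n_reviewed": 4, "n_rereviewed": 1,
            "n_agree_reviewed": 3, "n_passive_agree": 2,
            "review_time_total_s": 12.0, "classify_delay_mean_s": 2.0,
            "n_map_selections": 2, "n_map_allowed": 3,
            "reliance_slider": 0.7, "n_screen_switches": 4,
        }
        f = extract_embedded(rec)
        assert len(f) == 16
        assert f["emb_pct_reviewed"] == pytest.approx(40.0)
        assert f["emb_pct_ignored"] == pytest.approx(60.0)
        assert f["emb_explainability"] == 1.0

    def test_no_reviews_zero_review_time(self):
        rec = generate_embedded(1, 1, 1, "low", trust=1.0, reliance_slider=0.9,
                                trust_noise_sd=0.0)
        # full trust -> review probability at its floor (0) -> no review time
        assert rec["n_reviewed"] == 0
        f = extract_embedded(rec)
        assert f["emb_review_time_total"] == 0.0
        assert f["emb_pct_passive_agree"] == pytest.approx(100.0)


class TestFeatureVersions:
    def test_difference_and_ratio(self):
        assert apply_feature_version(10.0, pretrial_b=8.0, version=1) == pytest.approx(2.0)
        assert apply_feature_version(10.0, pretrial_b=8.0, version=4) == pytest.approx(1.25)

    def test_participant_standardization(self):
        # participant values {1,2,3}: mu=2, sd=1 -> v7(3)=1, v8(3)=1
        assert apply_feature_version(
            3.0, participant_mean=2.0, participant_sd=1.0, version=7
        ) == pytest.approx(1.0)
        assert apply_feature_version(3.0, participant_mean=2.0, version=8) == pytest.approx(1.0)

    def test_identity_at_preexp_baseline(self):
        assert apply_feature_version(5.0, preexp_b=5.0, version=3) == pytest.approx(0.0)
        assert apply_feature_version(5.0, preexp_b=5.0, version=6) == pytest.approx(1.0)

    def test_zero_sigma_never_infinite(self):
        v = apply_feature_version(3.0, participant_mean=2.0, participant_sd=0.0, version=7)
        assert np.isnan(v)
        v_eq = apply_feature_version(2.0, participant_mean=2.0, participant_sd=0.0, version=7)
        assert v_eq == 0.0

    def test_unknown_version_rejected(self):
        with pytest.raises(ValueError):
            apply_feature_version(1.0, version=9)
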