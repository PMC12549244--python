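"""Per-stream feature extraction.

Every extractor returns an ``OrderedDict``-like plain dict whose keys are
exactly the dictionary's names for that category, in order.  Features that
cannot be computed (too few beats, no SCRs, no blink pairs, ...) are NaN and
are filled later by hierarchical imputation.

Units: RR statistics in ms, HR in bpm, spectral HRV powers in ms², EDA in
µS (AUC in µS·s, slopes per s), respiration intervals in s, EEG band powers
in µV², fNIRS in µM, pupil in mm, times in s.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.stats import kurtosis, skew

from physiotrust.features.dictionary import (
    ECG_FEATURES,
    EDA_FEATURES,
    EEG_FEATURES,
    EEG_REGIONS,
    EYE_FEATURES,
    FNIRS_FEATURES,
    RSP_FEATURES,
    _FNIRS_HBO_STATS,
    _FNIRS_HBR_STATS,
)
from physiotrust.preprocess import (
    clean_eda,
    decompose_eda,
    detect_breaths,
    detect_r_peaks,
    filter_ecg,
    filter_fnirs,
    filter_resp,
    preprocess_eeg,
)
from physiotrust.preprocess.eda import EDA_FS
from physiotrust.synth.embedded import BACKGROUND_MEASURES, EMBEDDED_MEASURES
from physiotrust.synth.signals import EEG_BANDS, EEG_CHANNELS

__all__ = [
    "extract_ecg_features",
    "extract_eda_features",
    "extract_resp_features",
    "extract_eeg_features",
    "extract_fnirs_features",
    "extract_eye_features",
    "extract_embedded",
    "extract_background",
    "extract_epoch_features",
    "extract_signal_features",
]


def _nan_dict(names) -> dict:
    return {n: np.nan for n in names}


def _series_stats(x: np.ndarray, fs: float) -> dict:
    """mean, sd, min, max, range, slope (per s), auc (unit*s), skew, kurt."""
    t = np.arange(x.size) / fs
    slope = np.polyfit(t, x, 1)[0] if x.size > 1 else np.nan
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "range": float(np.ptp(x)),
        "slope": float(slope),
        "auc": float(np.trapezoid(x, t)),
        "skew": float(skew(x)) if x.size > 2 else np.nan,
        "kurt": float(kurtosis(x)) if x.size > 3 else np.nan,
    }


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    m = (freqs >= lo) & (freqs <= hi)
    if not m.any():
        return 0.0
    if m.sum() == 1:  # single bin: rectangle rule
        df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
        return float(psd[..., m][0] * df)
    return float(np.trapezoid(psd[..., m], freqs[m], axis=-1))


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

def extract_ecg_features(r_peaks: np.ndarray, epoch_s: float) -> dict:
    """28 heart-rate-variability features from R-peak times (s)."""
    r = np.asarray(r_peaks, dtype=float)
    if r.size < 3:
        return _nan_dict(ECG_FEATURES)
    rr = np.diff(r) * 1000.0  # ms
    drr = np.diff(rr)
    sdnn = float(np.std(rr, ddof=1))
    sdsd = float(np.std(drr, ddof=1)) if drr.size > 1 else 0.0
    rmssd = float(np.sqrt(np.mean(drr**2))) if drr.size else 0.0
    hr = 60000.0 / rr

    out = {
        "ecg_rr_mean": float(np.mean(rr)),
        "ecg_rr_median": float(np.median(rr)),
        "ecg_sdnn": sdnn,
        "ecg_rmssd": rmssd,
        "ecg_sdsd": sdsd,
        "ecg_pnn50": float(np.mean(np.abs(drr) > 50.0) * 100.0) if drr.size else 0.0,
        "ecg_pnn20": float(np.mean(np.abs(drr) > 20.0) * 100.0) if drr.size else 0.0,
        "ecg_rr_min": float(np.min(rr)),
        "ecg_rr_max": float(np.max(rr)),
        "ecg_rr_range": float(np.ptp(rr)),
        "ecg_rr_cv": sdnn / float(np.mean(rr)),
        "ecg_hr_mean": float(np.mean(hr)),
        "ecg_hr_min": float(np.min(hr)),
        "ecg_hr_max": float(np.max(hr)),
        "ecg_rr_skew": float(skew(rr)),
        "ecg_rr_kurt": float(kurtosis(rr)),
    }

    # spectral HRV: RR tachogram resampled at 4 Hz
    fs_i = 4.0
    t_mid = r[1:]
    if t_mid[-1] - t_mid[0] > 2.0:
        tt = np.arange(t_mid[0], t_mid[-1], 1.0 / fs_i)
        rr_i = np.interp(tt, t_mid, rr)
        rr_i = rr_i - np.mean(rr_i)
        nper = min(256, rr_i.size)
        f, P = sps.welch(rr_i, fs=fs_i, nperseg=nper)
        vlf = _band_power(f, P, 0.003, 0.04)
        lf = _band_power(f, P, 0.04, 0.15)
        hf = _band_power(f, P, 0.15, 0.4)
        tot = _band_power(f, P, 0.003, 0.4)

        def peak_freq(lo, hi):
            m = (f >= lo) & (f <= hi)
            if not m.any() or P[m].max() <= 0:
                return np.nan
            return float(f[m][np.argmax(P[m])])

        out.update({
            "ecg_vlf_power": vlf,
            "ecg_lf_power": lf,
            "ecg_hf_power": hf,
            "ecg_total_power": tot,
            "ecg_lf_hf": lf / hf if hf > 0 else np.nan,
            "ecg_lf_nu": 100.0 * lf / (lf + hf) if lf + hf > 0 else np.nan,
            "ecg_hf_nu": 100.0 * hf / (lf + hf) if lf + hf > 0 else np.nan,
            "ecg_lf_peak": peak_freq(0.04, 0.15),
            "ecg_hf_peak": peak_freq(0.15, 0.4),
        })
    else:
        out.update({n: np.nan for n in ECG_FEATURES[16:25]})

    sd1 = np.sqrt(0.5) * sdsd
    sd2sq = 2.0 * sdnn**2 - 0.5 * sdsd**2
    sd2 = float(np.sqrt(sd2sq)) if sd2sq > 0 else 0.0
    out["ecg_sd1"] = float(sd1)
    out["ecg_sd2"] = sd2
    out["ecg_sd1_sd2"] = float(sd1 / sd2) if sd2 > 0 else np.nan
    assert tuple(out) == ECG_FEATURES
    return out


# ---------------------------------------------------------------------------
# EDA
# ---------------------------------------------------------------------------

def extract_eda_features(
    raw10: np.ndarray,
    tonic: np.ndarray,
    phasic: np.ndarray,
    scr_events,
    fs: float = EDA_FS,
    driver: np.ndarray | None = None,
) -> dict:
    """63 electrodermal features from the 10-Hz decomposition outputs."""
    epoch_s = raw10.size / fs
    if driver is None:
        driver = np.clip(phasic, 0.0, None)
    out = {}
    for src_name, series in (
        ("scl", raw10), ("tonic", tonic), ("phasic", phasic), ("driver", driver)
    ):
        st = _series_stats(np.asarray(series, dtype=float), fs)
        for k, v in st.items():
            out[f"eda_{src_name}_{k}"] = v
    deriv = np.gradient(np.asarray(raw10, dtype=float)) * fs  # µS/s
    for k, v in _series_stats(deriv, fs).items():
        out[f"eda_deriv_{k}"] = v

    ev = list(scr_events)
    n = len(ev)
    out["eda_scr_count"] = float(n)
    out["eda_scr_rate"] = float(n / epoch_s * 60.0)
    if n:
        amps = np.array([e.amplitude_uS for e in ev])
        rises = np.array([e.rise_time_s for e in ev])
        recs = np.array([e.half_recovery_s for e in ev])
        recs = recs[np.isfinite(recs)]
        onsets = np.array([e.onset_s for e in ev])
        out.update({
            "eda_scr_amp_mean": float(amps.mean()),
            "eda_scr_amp_sd": float(amps.std(ddof=1)) if n > 1 else 0.0,
            "eda_scr_amp_max": float(amps.max()),
            "eda_scr_amp_min": float(amps.min()),
            "eda_scr_amp_sum": float(amps.sum()),
            "eda_scr_rise_mean": float(rises.mean()),
            "eda_scr_rise_sd": float(rises.std(ddof=1)) if n > 1 else 0.0,
            "eda_scr_rise_max": float(rises.max()),
            "eda_scr_rec_mean": float(recs.mean()) if recs.size else np.nan,
            "eda_scr_rec_sd": float(recs.std(ddof=1)) if recs.size > 1 else (
                0.0 if recs.size == 1 else np.nan
            ),
            "eda_scr_rec_max": float(recs.max()) if recs.size else np.nan,
            "eda_scr_first_latency": float(onsets[0]),
            "eda_iscr": float(np.trapezoid(np.clip(phasic, 0, None), dx=1.0 / fs)),
            "eda_scr_isi_mean": float(np.diff(onsets).mean()) if n > 1 else np.nan,
            "eda_scr_isi_sd": (
                float(np.diff(onsets).std(ddof=1)) if n > 2 else (0.0 if n == 2 else np.nan)
            ),
        })
        in_scr = np.zeros(raw10.size, dtype=bool)
        for e in ev:
            dur = e.rise_time_s + (
                2.0 * e.half_recovery_s if np.isfinite(e.half_recovery_s) else 4.0
            )
            lo = int(e.onset_s * fs)
            hi = min(raw10.size, int((e.onset_s + dur) * fs) + 1)
            in_scr[lo:hi] = True
        out["eda_scr_time_frac"] = float(in_scr.mean())
    else:
        for name in EDA_FEATURES:
            if name.startswith("eda_scr_") and name not in ("eda_scr_count", "eda_scr_rate"):
                out[name] = np.nan
        out["eda_iscr"] = float(np.trapezoid(np.clip(phasic, 0, None), dx=1.0 / fs))
        out["eda_scr_time_frac"] = 0.0
    out = {k: out[k] for k in EDA_FEATURES}
    return out


# ---------------------------------------------------------------------------
# Respiration
# ---------------------------------------------------------------------------

def extract_resp_features(filtered: np.ndarray, cycle_times: np.ndarray, fs: float) -> dict:
    """28 respiration features from the band-passed signal and cycle starts."""
    x = np.asarray(filtered, dtype=float)
    cyc = np.asarray(cycle_times, dtype=float)
    if cyc.size < 2:
        return _nan_dict(RSP_FEATURES)
    bi = np.diff(cyc)
    out = {
        "rsp_bi_mean": float(bi.mean()),
        "rsp_bi_sd": float(bi.std(ddof=1)) if bi.size > 1 else 0.0,
        "rsp_bi_min": float(bi.min()),
        "rsp_bi_max": float(bi.max()),
        "rsp_bi_range": float(np.ptp(bi)),
        "rsp_bi_cv": float(bi.std(ddof=1) / bi.mean()) if bi.size > 1 else 0.0,
        "rsp_bi_skew": float(skew(bi)) if bi.size > 2 else np.nan,
        "rsp_bi_kurt": float(kurtosis(bi)) if bi.size > 3 else np.nan,
        "rsp_rate": float(60.0 / bi.mean()),
    }

    # inhale = preceding trough -> peak, exhale = peak -> following trough
    min_dist = max(1, int(0.25 * bi.mean() * fs))
    pk, _ = sps.find_peaks(x, distance=min_dist)
    tr, _ = sps.find_peaks(-x, distance=min_dist)
    amps, inhales, exhales = [], [], []
    for p in pk:
        prev = tr[tr < p]
        nxt = tr[tr > p]
        if prev.size == 0 or nxt.size == 0:
            continue
        t0, t1 = prev[-1], nxt[0]
        inhales.append((p - t0) / fs)
        exhales.append((t1 - p) / fs)
        amps.append(0.5 * (x[p] - 0.5 * (x[t0] + x[t1])))
    amps = np.asarray(amps)
    if amps.size:
        out.update({
            "rsp_amp_mean": float(amps.mean()),
            "rsp_amp_sd": float(amps.std(ddof=1)) if amps.size > 1 else 0.0,
            "rsp_amp_min": float(amps.min()),
            "rsp_amp_max": float(amps.max()),
            "rsp_amp_range": float(np.ptp(amps)),
            "rsp_amp_cv": float(amps.std(ddof=1) / amps.mean()) if amps.size > 1 else 0.0,
        })
        inh, exh = np.asarray(inhales), np.asarray(exhales)
        out.update({
            "rsp_inhale_mean": float(inh.mean()),
            "rsp_exhale_mean": float(exh.mean()),
            "rsp_inhale_sd": float(inh.std(ddof=1)) if inh.size > 1 else 0.0,
            "rsp_exhale_sd": float(exh.std(ddof=1)) if exh.size > 1 else 0.0,
            "rsp_ie_ratio": float(inh.mean() / exh.mean()) if exh.mean() > 0 else np.nan,
        })
    else:
        for name in RSP_FEATURES[9:20]:
            out[name] = np.nan

    for k, v in _series_stats(x, fs).items():
        if k in ("mean", "sd", "skew", "kurt", "slope", "auc"):
            out[f"rsp_sig_{k}"] = v
    out["rsp_sig_rms"] = float(np.sqrt(np.mean(x**2)))

    nper = min(int(20 * fs), x.size)
    f, P = sps.welch(x, fs=fs, nperseg=nper)
    m = (f >= 0.05) & (f <= 3.0)
    out["rsp_dom_freq"] = float(f[m][np.argmax(P[m])]) if m.any() else np.nan
    out = {k: out[k] for k in RSP_FEATURES}
    return out


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def extract_eeg_features(
    cleaned: np.ndarray, fs: float, channels=EEG_CHANNELS
) -> dict:
    """125 band-power features: per-channel Welch PSD integrals over the five
    canonical bands, plus six region means.  Gamma is integrated to the 55-Hz
    filter edge."""
    x = np.asarray(cleaned, dtype=float)
    if x.ndim != 2 or x.shape[0] != len(channels):
        raise ValueError(f"expected ({len(channels)}, n) array, got {x.shape}")
    nper = min(int(2 * fs), x.shape[1])
    f, P = sps.welch(x, fs=fs, nperseg=nper, axis=-1)
    out = {}
    chan_power = {}
    for ci, ch in enumerate(channels):
        for band, (lo, hi) in EEG_BANDS.items():
            p = _band_power(f, P[ci], lo, hi)
            out[f"eeg_{ch}_{band}"] = p
            chan_power[(ch, band)] = p
    for region, members in EEG_REGIONS.items():
        for band in EEG_BANDS:
            out[f"eeg_{region}_{band}"] = float(
                np.mean([chan_power[(ch, band)] for ch in members])
            )
    out = {k: out[k] for k in EEG_FEATURES}
    return out


# ---------------------------------------------------------------------------
# fNIRS
# ---------------------------------------------------------------------------

def extract_fnirs_features(hbo: np.ndarray, hbr: np.ndarray, fs: float) -> dict:
    """360 hemodynamic features: 9 per chromophore per channel (20 channels).

    HbO carries max amplitude and time-to-max; HbR min amplitude and
    time-to-min; both carry mean, variance, skew, kurtosis, RMS, slope, AUC.
    """
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    if hbo.shape != hbr.shape or hbo.ndim != 2 or hbo.shape[0] != 20:
        raise ValueError(f"expected paired (20, n) arrays, got {hbo.shape}/{hbr.shape}")
    t = np.arange(hbo.shape[1]) / fs
    out = {}
    # vectorized per-chromophore statistics over all 20 channels at once
    stats = {}
    for sp, arr in (("hbo", hbo), ("hbr", hbr)):
        n = arr.shape[1]
        slope = np.polyfit(t, arr.T, 1)[0] if n > 1 else np.full(20, np.nan)
        stats[sp] = {
            "max": arr.max(axis=1),
            "ttmax": t[np.argmax(arr, axis=1)],
            "min": arr.min(axis=1),
            "ttmin": t[np.argmin(arr, axis=1)],
            "mean": arr.mean(axis=1),
            "var": arr.var(axis=1, ddof=1) if n > 1 else np.zeros(20),
            "skew": skew(arr, axis=1),
            "kurt": kurtosis(arr, axis=1),
            "rms": np.sqrt(np.mean(arr**2, axis=1)),
            "slope": slope,
            "auc": np.trapezoid(arr, t, axis=1),
        }
    for c in range(20):
        for sp, names in (("hbo", _FNIRS_HBO_STATS), ("hbr", _FNIRS_HBR_STATS)):
            for st in names:
                out[f"fnirs_ch{c + 1:02d}_{sp}_{st}"] = float(stats[sp][st][c])
    out = {k: out[k] for k in FNIRS_FEATURES}
    return out


# ---------------------------------------------------------------------------
# Eye tracking
# ---------------------------------------------------------------------------

def extract_eye_features(bundle: dict, fs: float, epoch_s: float) -> dict:
    """37 oculometric features from the pupil series and event streams."""
    pupil = np.asarray(bundle["pupil"], dtype=float)
    valid = pupil > 0.5  # blink gaps are ~0 mm
    out = _nan_dict(EYE_FEATURES)

    if valid.sum() > 3:
        pv = pupil[valid]
        tv = np.arange(pupil.size)[valid] / fs
        out.update({
            "eye_pupil_mean": float(pv.mean()),
            "eye_pupil_sd": float(pv.std(ddof=1)),
            "eye_pupil_min": float(pv.min()),
            "eye_pupil_max": float(pv.max()),
            "eye_pupil_range": float(np.ptp(pv)),
            "eye_pupil_slope": float(np.polyfit(tv, pv, 1)[0]),
            "eye_pupil_skew": float(skew(pv)),
            "eye_pupil_kurt": float(kurtosis(pv)),
            "eye_pupil_rms": float(np.sqrt(np.mean(pv**2))),
        })
        both = valid[:-1] & valid[1:]
        if both.any():
            v = np.diff(pupil) * fs  # mm/s
            v = v[both]
            out["eye_pcv"] = float(v.min())
            out["eye_pdv"] = float(v.max())
            out["eye_mav"] = float(np.abs(v).mean())

    bl = bundle["blinks"]
    nb = len(bl["onset"])
    out["eye_blink_count"] = float(nb)
    out["eye_blink_rate"] = float(nb / epoch_s * 60.0)
    if nb:
        dur = np.asarray(bl["duration"], dtype=float)
        out["eye_blink_dur_mean"] = float(dur.mean())
        out["eye_blink_dur_sd"] = float(dur.std(ddof=1)) if nb > 1 else 0.0
        out["eye_blink_dur_min"] = float(dur.min())
        out["eye_blink_dur_max"] = float(dur.max())
        out["eye_closure_frac"] = float(dur.sum() / epoch_s)
        if nb > 1:
            ibi = np.diff(np.asarray(bl["onset"], dtype=float))
            out["eye_ibi_mean"] = float(ibi.mean())
            out["eye_ibi_sd"] = float(ibi.std(ddof=1)) if nb > 2 else 0.0
    else:
        out["eye_closure_frac"] = 0.0

    fx = bundle["fixations"]
    n_fix = len(fx["onset"])
    for a in range(4):
        sel = np.asarray(fx["aoi"]) == a
        out[f"eye_dwell_aoi{a + 1}"] = float(np.asarray(fx["duration"])[sel].sum())
        out[f"eye_fixcount_aoi{a + 1}"] = float(sel.sum())
    out["eye_fix_total"] = float(n_fix)
    if n_fix:
        dur = np.asarray(fx["duration"], dtype=float)
        out["eye_fix_dur_mean"] = float(dur.mean())
        out["eye_fix_dur_sd"] = float(dur.std(ddof=1)) if n_fix > 1 else 0.0

    sc = bundle["saccades"]
    n_sac = len(sc["onset"])
    out["eye_sacc_count"] = float(n_sac)
    out["eye_sacc_rate"] = float(n_sac / epoch_s * 60.0)
    if n_sac:
        out["eye_sacc_amp_mean"] = float(np.mean(sc["amplitude_deg"]))

    if n_fix > 1:
        aoi = np.asarray(fx["aoi"], dtype=int)
        pairs = list(zip(aoi[:-1], aoi[1:]))
        out["eye_aoi_trans_count"] = float(sum(a != b for a, b in pairs))
        _, counts = np.unique(np.array(pairs), axis=0, return_counts=True)
        p = counts / counts.sum()
        out["eye_aoi_trans_entropy"] = float(-(p * np.log2(p)).sum())
    out = {k: out[k] for k in EYE_FEATURES}
    return out


# ---------------------------------------------------------------------------
# Embedded measures & operator background
# ---------------------------------------------------------------------------

def extract_embedded(record: dict) -> dict:
    """The 16 task-interaction measures from a raw click/timing record.

    Percent measures are relative to the satellites presented in the epoch;
    the reliance slider is a trial-level value broadcast to the trial's
    epochs; explainability is the session's condition coded low=0/high=1.
    """
    n_sat = record["n_satellites"]
    n_rev = record["n_reviewed"]
    out = {
        "emb_session": float(record["session"]),
        "emb_trial": float(record["trial"]),
        "emb_epoch": float(record["epoch"]),
        "emb_review_time_total": float(record["review_time_total_s"]),
        "emb_review_time_mean": (
            float(record["review_time_total_s"] / n_rev) if n_rev else 0.0
        ),
        "emb_pct_reviewed": 100.0 * n_rev / n_sat,
        "emb_pct_ignored": 100.0 * (n_sat - n_rev) / n_sat,
        "emb_pct_agree": 100.0
        * (record["n_agree_reviewed"] + record["n_passive_agree"]) / n_sat,
        "emb_pct_passive_agree": 100.0 * record["n_passive_agree"] / n_sat,
        "emb_classify_delay_mean": float(record["classify_delay_mean_s"]),
        "emb_pct_rereviewed": 100.0 * record["n_rereviewed"] / n_rev if n_rev else 0.0,
        "emb_map_selections": float(record["n_map_selections"]),
        "emb_pct_map_interactions": 100.0
        * record["n_map_selections"] / record["n_map_allowed"],
        "emb_reliance_slider": float(record["reliance_slider"]),
        "emb_screen_switches": float(record["n_screen_switches"]),
        "emb_explainability": 1.0 if record["explainability"] == "high" else 0.0,
    }
    out = {k: out[k] for k in EMBEDDED_MEASURES}
    return out


def extract_background(record: dict) -> dict:
    """The 25 per-participant background values, in canonical order."""
    return {k: float(record[k]) for k in BACKGROUND_MEASURES}


# ---------------------------------------------------------------------------
# Epoch-level orchestration
# ---------------------------------------------------------------------------

def extract_signal_features(
    signals: dict, rates: dict, epoch_s: float, ica_seed: int = 0, run_ica: bool = True
) -> dict:
    """Run the full preprocess + extract chain on one signal bundle.

    ``signals`` maps stream name -> raw data (as produced by the synthetic
    generators); returns the 641 physiological base features.  Streams absent
    from ``signals`` yield NaN for their whole category.
    """
    out = {}
    if "ecg" in signals:
        filt = filter_ecg(signals["ecg"], rates["ecg"])
        peaks, _ = detect_r_peaks(filt, rates["ecg"])
        out.update(extract_ecg_features(peaks, epoch_s))
    else:
        out.update(_nan_dict(ECG_FEATURES))

    if "eda" in signals:
        clean10, usable = clean_eda(signals["eda"], rates["eda"])
        if usable:
            tonic, phasic, events = decompose_eda(clean10)
            out.update(extract_eda_features(clean10, tonic, phasic, events))
        else:
            out.update(_nan_dict(EDA_FEATURES))
    else:
        out.update(_nan_dict(EDA_FEATURES))

    if "rsp" in signals:
        filt = filter_resp(signals["rsp"], rates["rsp"])
        cycles, _ = detect_breaths(filt, rates["rsp"])
        out.update(extract_resp_features(filt, cycles, rates["rsp"]))
    else:
        out.update(_nan_dict(RSP_FEATURES))

    if "eeg" in signals:
        cleaned, _ = preprocess_eeg(
            signals["eeg"], rates["eeg"], run_ica=run_ica, seed=ica_seed
        )
        out.update(extract_eeg_features(cleaned, rates["eeg"]))
    else:
        out.update(_nan_dict(EEG_FEATURES))

    if "fnirs" in signals:
        hbo, hbr = signals["fnirs"]
        fo, fr = filter_fnirs(hbo, hbr, rates["fnirs"])
        out.update(extract_fnirs_features(fo, fr, rates["fnirs"]))
    else:
        out.update(_nan_dict(FNIRS_FEATURES))

    if "eye" in signals:
        out.update(extract_eye_features(signals["eye"], rates["eye"], epoch_s))
    else:
        out.update(_nan_dict(EYE_FEATURES))
    return out


def extract_epoch_features(record, rates: dict, epoch_s: float, run_ica: bool = True) -> dict:
    """Materialize a record's signals (skipping missing streams) and extract
    the physiological features; embedded/background are joined later."""
    signals = {}
    for stream in record.gen_params:
        if record.missing.get(stream, False):
            continue
        data, _ = record.signals(stream)
        signals[stream] = data
    seed = abs(hash(tuple(record.seeds.get("eeg", [0])))) % (2**31)
    return extract_signal_features(signals, rates, epoch_s, ica_seed=seed, run_ica=run_ica)
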