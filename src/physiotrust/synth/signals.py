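"""Stream-appropriate raw signal generators.

Each generator synthesizes one 45-s-class signal segment with controllable
physiological parameters and returns ``(data, truth)`` where ``truth`` is a
dict of the ground-truth parameters and event times actually realized, so
downstream estimators can be tested against the generator's own bookkeeping.

Signal physics, briefly:

* ECG — template P-QRS-T complexes placed at RR intervals drawn i.i.d.
  Normal(60/HR, hrv_sd); optional mains (60 Hz) contamination.
* EDA — slow tonic level plus biexponential (Bateman-kernel) skin
  conductance responses at Poisson event times.
* Respiration — quasi-sinusoidal breathing with rate jitter and drift.
* EEG — per-channel sums of band-limited noise scaled to target band powers
  on the canonical delta/theta/alpha/beta/gamma bands, plus shared blink
  transients projected onto a frontally weighted topography.
* fNIRS — hemodynamic response (double-gamma HRF) pulses plus slow drift and
  cardiac ripple on HbO, with anticorrelated HbR.
* Eye — pupil diameter series with blink gaps, plus fixation/saccade event
  streams over four areas of interest.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

__all__ = [
    "generate_ecg",
    "generate_eda",
    "generate_resp",
    "generate_eeg",
    "generate_fnirs",
    "generate_eye",
    "bateman",
    "canonical_hrf",
    "EEG_CHANNELS",
    "EEG_BANDS",
    "BLINK_TOPOGRAPHY",
]

#: 19-channel 10-20 montage labels, frontal to occipital.
EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
)

#: Canonical EEG frequency bands in Hz.  Gamma is nominally 30-80 Hz but the
#: preprocessing chain low-passes at 55 Hz, so power is computed over
#: 30-55 Hz downstream.
EEG_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 55.0),
}

#: Relative blink-artifact loading per channel (frontally dominated).
BLINK_TOPOGRAPHY: dict[str, float] = {
    "Fp1": 1.0, "Fp2": 1.0,
    "F7": 0.45, "F3": 0.45, "Fz": 0.45, "F4": 0.45, "F8": 0.45,
    "T7": 0.12, "C3": 0.12, "Cz": 0.12, "C4": 0.12, "T8": 0.12,
    "P7": 0.05, "P3": 0.05, "Pz": 0.05, "P4": 0.05, "P8": 0.05,
    "O1": 0.02, "O2": 0.02,
}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# ECG
# --------------------------------------------------------------------------

def _pqrst_template(t: np.ndarray) -> np.ndarray:
    """One cardiac cycle centered on the R wave at t=0 (amplitudes in mV)."""

    def g(mu, sigma, amp):
        return amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)

    return (
        g(-0.20, 0.025, 0.15)   # P
        + g(-0.025, 0.010, -0.15)  # Q
        + g(0.0, 0.012, 1.0)    # R
        + g(0.030, 0.012, -0.25)  # S
        + g(0.25, 0.06, 0.30)   # T
    )


def generate_ecg(
    duration_s: float,
    mean_hr_bpm: float = 72.0,
    hrv_sd_ms: float = 40.0,
    fs: float = 500.0,
    seed=0,
    noise_uv: float = 0.01,
    mains_amp: float = 0.0,
    mains_hz: float = 60.0,
):
    """Synthesize a single-lead ECG with known R-peak times.

    Returns ``(waveform, truth)``; ``truth["r_peaks"]`` holds the true R-peak
    times (s) and ``truth["rr_intervals"]`` the realized RR series (s).
    """
    if not (30.0 <= mean_hr_bpm <= 200.0):
        raise ValueError(f"mean_hr_bpm must be in [30, 200], got {mean_hr_bpm}")
    mean_rr = 60.0 / mean_hr_bpm
    if duration_s < mean_rr:
        raise ValueError("duration shorter than one beat")
    if fs <= 0 or duration_s <= 0:
        raise ValueError("fs and duration_s must be positive")

    rng = _rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    # draw more beats than can fit, then truncate
    n_draw = int(np.ceil(duration_s / mean_rr * 1.5)) + 8
    rr = rng.normal(mean_rr, hrv_sd_ms / 1000.0, size=n_draw)
    rr = np.clip(rr, 0.3, 2.0)
    beat_times = np.cumsum(rr) - rr[0] + 0.1  # first beat shortly after start
    beat_times = beat_times[beat_times < duration_s - 0.05]

    x = np.zeros(n)
    half = 0.45  # template support half-width in s
    for bt in beat_times:
        lo = max(0, int((bt - half) * fs))
        hi = min(n, int((bt + half) * fs) + 1)
        x[lo:hi] += _pqrst_template(t[lo:hi] - bt)

    x += noise_uv * rng.standard_normal(n)
    if mains_amp > 0:
        x += mains_amp * np.sin(2 * np.pi * mains_hz * t)

    rr_real = np.diff(beat_times)
    truth = {
        "r_peaks": beat_times,
        "rr_intervals": rr_real,
        "mean_hr_bpm": mean_hr_bpm,
        "hrv_sd_ms": hrv_sd_ms,
        "fs": fs,
    }
    return x, truth


# --------------------------------------------------------------------------
# EDA
# --------------------------------------------------------------------------

def bateman(t: np.ndarray, tau_rise: float = 0.75, tau_decay: float = 2.0) -> np.ndarray:
    """Biexponential SCR impulse response, normalized to unit peak."""
    k = np.where(t >= 0, np.exp(-t / tau_decay) - np.exp(-t / tau_rise), 0.0)
    t_peak = np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    return k / peak


def generate_eda(
    duration_s: float,
    tonic_level_uS: float = 8.0,
    scr_rate_per_min: float = 6.0,
    scr_amp_uS: float = 0.4,
    fs: float = 32.0,
    seed=0,
    drift_amp_uS: float = 0.15,
    amp_cv: float = 0.15,
    noise_uS: float = 0.005,
    scr_times: np.ndarray | None = None,
):
    """Synthesize skin conductance = slow tonic drift + Bateman SCR pulses.

    SCR onsets are Poisson with rate ``scr_rate_per_min`` unless explicit
    ``scr_times`` are given; per-event peak amplitudes are drawn around
    ``scr_amp_uS`` with coefficient of variation ``amp_cv``.
    """
    if not (1.0 <= tonic_level_uS <= 40.0):
        raise ValueError(f"tonic_level_uS must be in [1, 40], got {tonic_level_uS}")
    if scr_rate_per_min < 0 or scr_amp_uS < 0:
        raise ValueError("scr rate and amplitude must be non-negative")
    rng = _rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    # smooth tonic drift: two incommensurate slow sinusoids with random phase
    ph = rng.uniform(0, 2 * np.pi, size=2)
    tonic = (
        tonic_level_uS
        + drift_amp_uS * np.sin(2 * np.pi * 0.009 * t + ph[0])
        + 0.5 * drift_amp_uS * np.sin(2 * np.pi * 0.021 * t + ph[1])
    )

    if scr_times is None:
        n_ev = rng.poisson(scr_rate_per_min * duration_s / 60.0)
        onsets = np.sort(rng.uniform(0.0, max(duration_s - 3.0, 0.1), size=n_ev))
    else:
        onsets = np.asarray(scr_times, dtype=float)
    amps = np.abs(rng.normal(scr_amp_uS, amp_cv * scr_amp_uS, size=len(onsets)))

    phasic = np.zeros(n)
    for on, a in zip(onsets, amps):
        phasic += a * bateman(t - on)

    x = tonic + phasic + noise_uS * rng.standard_normal(n)
    truth = {
        "tonic": tonic,
        "phasic": phasic,
        "scr_onsets": onsets,
        "scr_amplitudes": amps,
        "tonic_level_uS": tonic_level_uS,
        "scr_rate_per_min": scr_rate_per_min,
        "fs": fs,
    }
    return x, truth


# --------------------------------------------------------------------------
# Respiration
# --------------------------------------------------------------------------

def generate_resp(
    duration_s: float,
    rate_bpm: float = 15.0,
    amplitude: float = 1.0,
    fs: float = 32.0,
    seed=0,
    rate_jitter: float = 0.03,
    noise: float = 0.01,
    drift_amp: float = 0.05,
):
    """Quasi-sinusoidal chest-band respiration with true breath-cycle times."""
    if not (3.0 <= rate_bpm <= 180.0):
        raise ValueError(f"rate_bpm must be in [3, 180], got {rate_bpm}")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    rng = _rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    f0 = rate_bpm / 60.0
    # slowly varying instantaneous rate
    inst = f0 * (1.0 + rate_jitter * np.sin(2 * np.pi * 0.02 * t + rng.uniform(0, 2 * np.pi)))
    phase = 2 * np.pi * np.cumsum(inst) / fs
    x = amplitude * np.sin(phase)
    x += drift_amp * np.sin(2 * np.pi * 0.008 * t + rng.uniform(0, 2 * np.pi))
    x += noise * rng.standard_normal(n)

    # true cycle starts: upward zero crossings of the phase modulo 2π
    cyc = np.floor(phase / (2 * np.pi))
    starts = np.flatnonzero(np.diff(cyc) > 0) + 1
    cycle_times = t[starts]
    truth = {
        "cycle_times": cycle_times,
        "rate_bpm": rate_bpm,
        "amplitude": amplitude,
        "fs": fs,
    }
    return x, truth


# --------------------------------------------------------------------------
# EEG
# --------------------------------------------------------------------------

DEFAULT_BAND_POWER: dict[str, float] = {
    # broadly 1/f-shaped resting spectrum, µV² per band
    "delta": 30.0,
    "theta": 15.0,
    "alpha": 20.0,
    "beta": 8.0,
    "gamma": 3.0,
}


def generate_eeg(
    duration_s: float,
    n_channels: int = 19,
    band_power_targets: dict | None = None,
    blink_rate_per_min: float = 12.0,
    fs: float = 250.0,
    seed=0,
    blink_amp_uv: float = 120.0,
    allow_channel_override: bool = False,
):
    """Multichannel EEG as band-limited noise with target band powers.

    ``band_power_targets`` maps band name -> power (µV²), scalar or length-19
    per-channel array.  Blink transients are shared across channels through a
    frontally weighted topography.  Returns ``(data, truth)`` with ``data``
    of shape (n_channels, n_samples).
    """
    if n_channels != 19 and not allow_channel_override:
        raise ValueError("n_channels != 19 requires allow_channel_override=True")
    targets = dict(DEFAULT_BAND_POWER)
    if band_power_targets:
        unknown = set(band_power_targets) - set(EEG_BANDS)
        if unknown:
            raise ValueError(f"unknown EEG bands: {sorted(unknown)}")
        targets.update(band_power_targets)

    rng = _rng(seed)
    n = int(round(duration_s * fs))
    labels = EEG_CHANNELS[:n_channels] if n_channels <= 19 else tuple(
        f"ch{i}" for i in range(n_channels)
    )
    data = np.zeros((n_channels, n))
    realized = {}
    pad = int(2 * fs)  # discard filter transients
    for band, (lo, hi) in EEG_BANDS.items():
        tgt = np.broadcast_to(np.asarray(targets[band], dtype=float), (n_channels,))
        sos = sps.butter(4, [lo / (fs / 2), min(hi / (fs / 2), 0.99)], btype="band", output="sos")
        noise = rng.standard_normal((n_channels, n + 2 * pad))
        comp = sps.sosfiltfilt(sos, noise, axis=1)[:, pad:pad + n]
        var = comp.var(axis=1)
        var[var == 0] = 1.0
        comp *= np.sqrt(tgt / var)[:, None]
        data += comp
        realized[band] = tgt.copy()

    blink_times = np.array([])
    if blink_rate_per_min > 0:
        n_bl = rng.poisson(blink_rate_per_min * duration_s / 60.0)
        blink_times = np.sort(rng.uniform(0.2, max(duration_s - 0.5, 0.3), size=n_bl))
        t = np.arange(n) / fs
        topo = np.array([BLINK_TOPOGRAPHY.get(lbl, 0.1) for lbl in labels])
        bump = np.zeros(n)
        for bt in blink_times:
            bump += np.exp(-0.5 * ((t - bt) / 0.08) ** 2)
        data += blink_amp_uv * topo[:, None] * bump[None, :]

    truth = {
        "band_power": realized,
        "blink_times": blink_times,
        "channels": labels,
        "fs": fs,
    }
    return data, truth


# --------------------------------------------------------------------------
# fNIRS
# --------------------------------------------------------------------------

def canonical_hrf(t: np.ndarray, time_to_peak: float = 6.0, undershoot: float = 16.0) -> np.ndarray:
    """Double-gamma hemodynamic response, unit peak, time in s."""
    from scipy.stats import gamma as gamma_dist

    t = np.asarray(t, dtype=float)
    h = np.zeros_like(t)
    pos = t > 0
    # shape/scale chosen so the positive lobe peaks at time_to_peak
    a1 = 6.0
    b1 = time_to_peak / (a1 - 1)
    a2 = 16.0
    b2 = undershoot / (a2 - 1)
    h[pos] = gamma_dist.pdf(t[pos], a1, scale=b1) - 0.35 * gamma_dist.pdf(t[pos], a2, scale=b2)
    peak = gamma_dist.pdf(time_to_peak, a1, scale=b1) - 0.35 * gamma_dist.pdf(
        time_to_peak, a2, scale=b2
    )
    return h / peak


def generate_fnirs(
    duration_s: float,
    n_channels: int = 20,
    activation_amp: float | np.ndarray = 1.0,
    time_to_peak_s: float = 6.0,
    event_times: np.ndarray | None = None,
    fs: float = 10.0,
    seed=0,
    drift_amp: float = 0.4,
    cardiac_amp: float = 0.08,
    noise: float = 0.03,
    hbr_ratio: float = -0.4,
):
    """HbO/HbR concentration series with HRF pulses, drift and cardiac ripple.

    Returns ``((hbo, hbr), truth)`` with arrays of shape
    (n_channels, n_samples); amplitudes in µM.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if fs <= 2.0:
        raise ValueError("fnirs fs must exceed 2 Hz to carry cardiac ripple")
    rng = _rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    amps = np.broadcast_to(np.asarray(activation_amp, dtype=float), (n_channels,))

    if event_times is None:
        n_ev = max(1, rng.poisson(duration_s / 20.0))
        event_times = np.sort(rng.uniform(0.0, max(duration_s - 8.0, 1.0), size=n_ev))
    event_times = np.asarray(event_times, dtype=float)

    act = np.zeros(n)
    for ev in event_times:
        act += canonical_hrf(t - ev, time_to_peak=time_to_peak_s)

    hbo = np.empty((n_channels, n))
    hbr = np.empty((n_channels, n))
    for c in range(n_channels):
        ph = rng.uniform(0, 2 * np.pi, size=3)
        drift = drift_amp * np.sin(2 * np.pi * 0.005 * t + ph[0]) + 0.1 * drift_amp * t / max(
            duration_s, 1.0
        )
        cardiac = cardiac_amp * np.sin(2 * np.pi * 1.1 * t + ph[1])
        clean = amps[c] * act
        hbo[c] = clean + drift + cardiac + noise * rng.standard_normal(n)
        hbr[c] = hbr_ratio * clean - 0.5 * drift + 0.3 * cardiac_amp * np.sin(
            2 * np.pi * 1.1 * t + ph[2]
        ) + noise * rng.standard_normal(n)

    truth = {
        "event_times": event_times,
        "time_to_peak_s": time_to_peak_s,
        "activation_amp": amps.copy(),
        "fs": fs,
    }
    return (hbo, hbr), truth


# --------------------------------------------------------------------------
# Eye tracking
# --------------------------------------------------------------------------

N_AOIS = 4


def generate_eye(
    duration_s: float,
    pupil_mean_mm: float = 3.5,
    blink_rate_per_min: float = 12.0,
    blink_dur_s: float = 0.18,
    fix_dur_s: float = 0.45,
    saccade_amp_deg: float = 6.0,
    aoi_weights: np.ndarray | None = None,
    fs: float = 120.0,
    seed=0,
):
    """Pupil series plus blink / fixation / saccade event streams.

    Fixations alternate with saccades; each fixation is assigned one of four
    areas of interest with probabilities ``aoi_weights``.  Returns
    ``(bundle, truth)`` where ``bundle`` has keys ``pupil`` (mm series),
    ``blinks`` (onset, duration), ``fixations`` (onset, duration, aoi) and
    ``saccades`` (onset, amplitude_deg).
    """
    if not (1.5 <= pupil_mean_mm <= 9.0):
        raise ValueError("pupil_mean_mm outside physiological range [1.5, 9]")
    if min(blink_rate_per_min, blink_dur_s, fix_dur_s, saccade_amp_deg) < 0:
        raise ValueError("eye parameters must be non-negative")
    rng = _rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    pupil = (
        pupil_mean_mm
        + 0.15 * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
        + 0.03 * rng.standard_normal(n)
    )

    # blinks: Poisson onsets, pupil trace gap (drop to ~0 during closure)
    n_bl = rng.poisson(blink_rate_per_min * duration_s / 60.0)
    bl_on = np.sort(rng.uniform(0.0, max(duration_s - 0.4, 0.1), size=n_bl))
    bl_dur = np.abs(rng.normal(blink_dur_s, 0.1 * blink_dur_s if blink_dur_s else 0.0, size=n_bl))
    for on, d in zip(bl_on, bl_dur):
        lo, hi = int(on * fs), min(n, int((on + d) * fs) + 1)
        pupil[lo:hi] = 0.0

    # fixation / saccade alternation
    if aoi_weights is None:
        aoi_weights = np.array([0.4, 0.3, 0.2, 0.1])
    aoi_weights = np.asarray(aoi_weights, dtype=float)
    aoi_weights = aoi_weights / aoi_weights.sum()
    fix_on, fix_dur, fix_aoi, sac_on, sac_amp = [], [], [], [], []
    clock = rng.uniform(0.0, 0.2)
    while clock < duration_s - 0.05:
        d = max(0.08, rng.normal(fix_dur_s, 0.25 * fix_dur_s if fix_dur_s else 0.0))
        d = min(d, duration_s - clock)
        fix_on.append(clock)
        fix_dur.append(d)
        fix_aoi.append(int(rng.choice(N_AOIS, p=aoi_weights)))
        clock += d
        if clock >= duration_s - 0.05:
            break
        sac_on.append(clock)
        sac_amp.append(max(0.5, rng.normal(saccade_amp_deg, 0.2 * saccade_amp_deg)))
        clock += rng.uniform(0.02, 0.06)  # saccade flight time

    bundle = {
        "pupil": pupil,
        "blinks": {"onset": bl_on, "duration": bl_dur},
        "fixations": {
            "onset": np.array(fix_on),
            "duration": np.array(fix_dur),
            "aoi": np.array(fix_aoi, dtype=int),
        },
        "saccades": {"onset": np.array(sac_on), "amplitude_deg": np.array(sac_amp)},
    }
    truth = {
        "pupil_mean_mm": pupil_mean_mm,
        "blink_rate_per_min": blink_rate_per_min,
        "blink_dur_s": blink_dur_s,
        "fix_dur_s": fix_dur_s,
        "saccade_amp_deg": saccade_amp_deg,
        "fs": fs,
    }
    return bundle, truth
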