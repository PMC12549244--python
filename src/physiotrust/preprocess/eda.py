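"""EDA cleaning and continuous tonic/phasic decomposition.

Cleaning follows the artifact rule for finger electrodes: samples outside
the physiological 1-40 µS window are replaced by linear interpolation, the
series is smoothed with a 3rd-order Savitzky-Golay filter, and resampled to
10 Hz for decomposition.

The decomposition is a continuous-decomposition-style split: a slow tonic
level is estimated with a low-percentile filter (tracking the skin
conductance level underneath superposed responses) followed by low-pass
smoothing; the phasic component is the exact remainder, so
tonic + phasic reconstructs the input identically.  A sparse SCR driver is
recovered from the phasic component by Wiener deconvolution against a
Bateman kernel, and individual skin conductance responses above a 0.01 µS
amplitude threshold are characterized by onset, amplitude, rise time and
half-recovery time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import percentile_filter

from physiotrust.synth.signals import bateman

__all__ = ["clean_eda", "decompose_eda", "ScrEvent", "EDA_FS"]

EDA_FS = 10.0
SCR_AMP_THRESHOLD_US = 0.01


@dataclass(frozen=True)
class ScrEvent:
    """One skin conductance response."""

    onset_s: float
    amplitude_uS: float
    rise_time_s: float
    half_recovery_s: float  # NaN when recovery is not reached in-epoch


def clean_eda(raw: np.ndarray, fs: float):
    """Range-clean, smooth and resample EDA to 10 Hz.

    Returns ``(clean10, usable)``; ``usable`` is False when more than half
    of the input samples fell outside 1-40 µS.
    """
    x = np.asarray(raw, dtype=float).copy()
    if fs < EDA_FS:
        raise ValueError(f"EDA fs must be >= {EDA_FS} Hz, got {fs}")
    n = x.size
    bad = ~np.isfinite(x) | (x < 1.0) | (x > 40.0)
    usable = bool(bad.mean() <= 0.5)
    if bad.any():
        if bad.all():
            x[:] = 0.0
        else:
            idx = np.arange(n)
            x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])

    # Savitzky-Golay, polynomial order 3, ~1 s window
    win = int(fs) | 1
    if win <= 3:
        win = 5
    if win >= n:
        win = (n - 1) | 1
    if win > 3:
        x = sps.savgol_filter(x, win, polyorder=3)

    n_out = int(round(n * EDA_FS / fs))
    t_in = np.arange(n) / fs
    t_out = np.arange(n_out) / EDA_FS
    clean10 = np.interp(t_out, t_in, x)
    return clean10, usable


def _estimate_tonic(x: np.ndarray, fs: float) -> np.ndarray:
    """Slow conductance level: 10th-percentile filter over an 8-s window,
    then 0.05 Hz zero-phase low-pass."""
    win = max(3, int(8.0 * fs) | 1)
    base = percentile_filter(x, percentile=10, size=win, mode="nearest")
    sos = sps.butter(2, 0.05 / (fs / 2.0), btype="lowpass", output="sos")
    tonic = sps.sosfiltfilt(sos, base)
    # never exceed the signal envelope by more than the smoothing allows
    return tonic


def decompose_eda(
    clean10: np.ndarray,
    fs: float = EDA_FS,
    tau_rise: float = 0.75,
    tau_decay: float = 2.0,
):
    """Split 10-Hz EDA into tonic + phasic and list SCR events.

    Returns ``(tonic, phasic, events)``.  ``tonic + phasic`` equals the
    input exactly by construction.  SCR amplitudes are measured on the
    phasic component as peak minus onset level.
    """
    x = np.asarray(clean10, dtype=float)
    if x.size < int(30 * fs):
        raise ValueError("decomposition needs at least 30 s of 10 Hz EDA")
    n = x.size
    t = np.arange(n) / fs

    tonic = _estimate_tonic(x, fs)
    phasic = x - tonic

    if np.ptp(x) < 1e-9:  # constant input
        return tonic, phasic, []

    # Wiener deconvolution of the phasic component against the Bateman kernel
    kern = bateman(t - t[n // 2], tau_rise, tau_decay)
    kern = np.roll(kern, -(n // 2))
    K = np.fft.rfft(kern)
    P = np.fft.rfft(phasic)
    lam = 0.05 * np.max(np.abs(K)) ** 2
    driver = np.fft.irfft(P * np.conj(K) / (np.abs(K) ** 2 + lam), n=n)
    driver = np.clip(driver, 0.0, None)

    events = _find_scrs(phasic, driver, fs)
    return tonic, phasic, events


def _find_scrs(phasic: np.ndarray, driver: np.ndarray, fs: float):
    n = phasic.size
    if driver.max() <= 0:
        return []
    pk, _ = sps.find_peaks(driver, height=0.05 * driver.max(), distance=int(1.0 * fs))
    events = []
    for p in pk:
        # onset: local phasic minimum in the 3 s before the driver peak
        lo = max(0, p - int(3.0 * fs))
        onset_idx = lo + int(np.argmin(phasic[lo:p + 1])) if p > lo else p
        # peak of the phasic response after onset (within 5 s)
        hi = min(n, onset_idx + int(5.0 * fs))
        seg = phasic[onset_idx:hi]
        if seg.size < 2:
            continue
        peak_idx = onset_idx + int(np.argmax(seg))
        amp = phasic[peak_idx] - phasic[onset_idx]
        if amp < SCR_AMP_THRESHOLD_US:
            continue
        rise = (peak_idx - onset_idx) / fs
        if rise > 3.5:  # slower than any Bateman response: residual drift
            continue
        # half recovery: first time after the peak at which the response has
        # decayed to half its amplitude above onset level
        half_level = phasic[onset_idx] + 0.5 * amp
        rec = np.nan
        below = np.flatnonzero(phasic[peak_idx:] <= half_level)
        if below.size:
            rec = below[0] / fs
        events.append(
            ScrEvent(
                onset_s=onset_idx / fs,
                amplitude_uS=float(amp),
                rise_time_s=float(rise),
                half_recovery_s=float(rec),
            )
        )
    # strictly increasing, dedup near-coincident onsets
    events.sort(key=lambda e: e.onset_s)
    dedup = []
    for ev in events:
        if dedup and ev.onset_s - dedup[-1].onset_s < 0.5:
            if ev.amplitude_uS > dedup[-1].amplitude_uS:
                dedup[-1] = ev
            continue
        dedup.append(ev)
    return dedup
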