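"""Zero-phase IIR filter cascades for the waveform streams.

All filters are 4th-order Butterworth applied forward-backward
(``sosfiltfilt``), so the effective magnitude response is the square of the
one-pass response and the phase response is identically zero.  Output length
always equals input length.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

__all__ = ["zero_phase_sos", "filter_ecg", "filter_resp", "filter_fnirs"]

_ORDER = 4


def _check_finite(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    return x


def zero_phase_sos(
    x: np.ndarray,
    fs: float,
    btype: str,
    cutoff,
    order: int = _ORDER,
    axis: int = -1,
) -> np.ndarray:
    """Apply a zero-phase Butterworth filter along ``axis``."""
    wn = np.atleast_1d(np.asarray(cutoff, dtype=float)) / (fs / 2.0)
    if np.any(wn <= 0) or np.any(wn >= 1):
        raise ValueError(f"cutoff {cutoff} outside (0, fs/2) for fs={fs}")
    sos = sps.butter(order, wn if wn.size > 1 else wn[0], btype=btype, output="sos")
    return sps.sosfiltfilt(sos, x, axis=axis)


def filter_ecg(raw: np.ndarray, fs: float) -> np.ndarray:
    """ECG cleaning cascade: 1 Hz highpass (baseline wander), 100 Hz lowpass
    (EMG noise), 59-61 Hz bandstop (powerline), all zero-phase."""
    if fs <= 200:
        raise ValueError(f"ECG fs must exceed 200 Hz (100 Hz lowpass edge), got {fs}")
    x = _check_finite(raw)
    x = zero_phase_sos(x, fs, "highpass", 1.0)
    x = zero_phase_sos(x, fs, "lowpass", 100.0)
    x = zero_phase_sos(x, fs, "bandstop", (59.0, 61.0))
    return x


def filter_resp(raw: np.ndarray, fs: float) -> np.ndarray:
    """Respiration band-pass 0.05-3 Hz, preserving 3-180 breaths/min."""
    if fs <= 6:
        raise ValueError(f"respiration fs must exceed 6 Hz, got {fs}")
    x = _check_finite(raw)
    return zero_phase_sos(x, fs, "bandpass", (0.05, 3.0))


def filter_fnirs(hbo: np.ndarray, hbr: np.ndarray, fs: float):
    """Per-channel zero-phase band-pass 0.016-0.5 Hz on HbO and HbR.

    Removes slow drift and cardiac ripple while keeping the hemodynamic
    response band.  Accepts (n_channels, n_samples) arrays.
    """
    if fs <= 1.0:
        raise ValueError(f"fnirs fs must exceed 1 Hz for a 0.5 Hz upper edge, got {fs}")
    hbo = _check_finite(hbo)
    hbr = _check_finite(hbr)
    out_o = zero_phase_sos(hbo, fs, "bandpass", (0.016, 0.5), axis=-1)
    out_r = zero_phase_sos(hbr, fs, "bandpass", (0.016, 0.5), axis=-1)
    return out_o, out_r
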