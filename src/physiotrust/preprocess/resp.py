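"""Breath-cycle detection on band-passed respiration."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

__all__ = ["detect_breaths"]


def detect_breaths(filtered: np.ndarray, fs: float):
    """Return breath cycle start times (s) from a 0.05-3 Hz respiration band.

    Cycle starts are upward zero crossings confirmed by an intervening
    signal peak (so noise ripple around zero does not double-count).
    Returns ``(cycle_times, quality_ok)``.
    """
    x = np.asarray(filtered, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D waveform")
    sd = np.std(x)
    if sd < 1e-12:
        return np.array([]), False

    up = np.flatnonzero((x[:-1] <= 0) & (x[1:] > 0)) + 1
    if up.size == 0:
        return np.array([]), False

    # require a prominent peak between consecutive crossings
    peaks, _ = sps.find_peaks(x, height=0.3 * sd, distance=int(0.3 * fs))
    times = []
    for i, s in enumerate(up):
        nxt = up[i + 1] if i + 1 < up.size else x.size
        if np.any((peaks >= s) & (peaks < nxt)):
            times.append(s / fs)
    times = np.asarray(times)
    return times, bool(times.size >= 2)
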