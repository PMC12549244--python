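"""The eight baseline-normalization "versions".

Given an active-epoch raw feature value ``a``, the same feature computed
over the trial's pre-trial baseline ``b_trial``, the participant's
within-session mean pre-trial baseline ``b_mean``, the session's
pre-experimental baseline ``b_preexp`` and the participant's own
active-value statistics (mu, sigma):

    v1 = a - b_trial        v5 = a / b_mean
    v2 = a - b_mean         v6 = a / b_preexp
    v3 = a - b_preexp       v7 = (a - mu) / sigma
    v4 = a / b_trial        v8 = a - mu

Degenerate cells are defined rather than infinite: a ratio of a zero value
to its zero baseline is 1 ("no change"); a nonzero value over a zero
baseline is NaN (imputed later).  A z-score with sigma = 0 is 0 when the
value equals the mean, NaN otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["apply_feature_version", "VERSION_NAMES"]

VERSION_NAMES = {
    1: "pretrial difference",
    2: "mean-pretrial difference",
    3: "pre-experimental difference",
    4: "pretrial ratio",
    5: "mean-pretrial ratio",
    6: "pre-experimental ratio",
    7: "participant z-score",
    8: "participant centered",
}

_DENOM_EPS = 1e-12


def _safe_div(num, den, zero_zero=1.0):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.where(np.abs(den) > _DENOM_EPS, num / np.where(den == 0, 1.0, den), np.nan)
    both = (np.abs(den) <= _DENOM_EPS) & (np.abs(num) <= _DENOM_EPS)
    out = np.where(both, zero_zero, out)
    return out if out.ndim else float(out)


def apply_feature_version(
    active,
    pretrial_b=None,
    mean_pretrial_b=None,
    preexp_b=None,
    participant_mean=None,
    participant_sd=None,
    version: int = 1,
):
    """Apply one baselining version; scalar or elementwise on arrays."""
    a = np.asarray(active, dtype=float)
    if version == 1:
        out = a - np.asarray(pretrial_b, dtype=float)
    elif version == 2:
        out = a - np.asarray(mean_pretrial_b, dtype=float)
    elif version == 3:
        out = a - np.asarray(preexp_b, dtype=float)
    elif version == 4:
        out = _safe_div(a, pretrial_b)
    elif version == 5:
        out = _safe_div(a, mean_pretrial_b)
    elif version == 6:
        out = _safe_div(a, preexp_b)
    elif version == 7:
        out = _safe_div(a - np.asarray(participant_mean, dtype=float), participant_sd,
                        zero_zero=0.0)
    elif version == 8:
        out = a - np.asarray(participant_mean, dtype=float)
    else:
        raise ValueError(f"version must be 1..8, got {version}")
    if np.ndim(out) == 0:
        return float(out)
    return out
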