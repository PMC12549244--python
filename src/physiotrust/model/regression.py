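"""OLS refit and bounded trust prediction.

The relaxed step: each LASSO-selected predictor set is refit with ordinary
least squares (no shrinkage).  Exact rank deficiencies (duplicate or
perfectly collinear columns, which versions of one feature can produce) are
resolved by dropping dependent columns via pivoted QR, with a warning.
Predictions are capped to the [0, 1] trust scale; the uncapped values stay
available for diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = ["CandidateModel", "fit_ols", "predict_trust"]


@dataclass
class CandidateModel:
    """An OLS trust model on a named predictor subset."""

    predictors: tuple[str, ...]
    coef: np.ndarray
    intercept: float
    r2: float
    adj_r2: float
    n_obs: int
    loto_q2: float = np.nan
    dropped: tuple[str, ...] = field(default_factory=tuple)

    @property
    def p(self) -> int:
        return len(self.predictors)

    def predict_raw(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.predictors if c not in X.columns]
        if missing:
            raise KeyError(f"missing predictor columns: {missing[:5]}")
        return self.intercept + np.asarray(X[list(self.predictors)], dtype=float) @ self.coef

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "loto_q2": self.loto_q2,
            "n_obs": self.n_obs,
            "dropped": list(self.dropped),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CandidateModel":
        return cls(
            predictors=tuple(d["predictors"]),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            r2=float(d["r2"]),
            adj_r2=float(d["adj_r2"]),
            n_obs=int(d["n_obs"]),
            loto_q2=float(d.get("loto_q2", np.nan)),
            dropped=tuple(d.get("dropped", ())),
        )


def _independent_columns(A: np.ndarray, tol_factor: float = 1e-10):
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    if A.shape[1] == 0:
        return np.array([], dtype=int)
    _, R, piv = linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] == 0:
        return np.array([], dtype=int)
    rank = int(np.sum(diag > tol_factor * diag[0]))
    return np.sort(piv[:rank])


def fit_ols(X: pd.DataFrame, y, predictors=None) -> CandidateModel:
    """Fit y ~ X[predictors] by least squares with an intercept.

    Rank-deficient subsets drop exactly dependent columns (warned) and
    refit on the remainder.
    """
    if predictors is None:
        predictors = list(X.columns)
    predictors = list(predictors)
    yv = np.asarray(y, dtype=float)
    n = yv.size
    if n <= len(predictors) + 1:
        raise ValueError(
            f"need n > p + 1 for OLS, got n={n}, p={len(predictors)}"
        )
    A = np.asarray(X[predictors], dtype=float)
    keep = _independent_columns(np.column_stack([np.ones(n), A]))
    keep_pred = [predictors[i - 1] for i in keep if i > 0]
    dropped = tuple(c for c in predictors if c not in keep_pred)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} exactly collinear predictor(s)",
            stacklevel=2,
        )
        A = np.asarray(X[keep_pred], dtype=float)
    design = np.column_stack([np.ones(n), A])
    beta, *_ = np.linalg.lstsq(design, yv, rcond=None)
    fitted = design @ beta
    ss_res = float(np.sum((yv - fitted) ** 2))
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    p = len(keep_pred)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else np.nan
    return CandidateModel(
        predictors=tuple(keep_pred),
        coef=beta[1:],
        intercept=float(beta[0]),
        r2=r2,
        adj_r2=adj,
        n_obs=n,
        dropped=dropped,
    )


def predict_trust(model: CandidateModel, X_new: pd.DataFrame):
    """Bounded trust predictions.

    Returns ``(capped, n_capped, raw)``: predictions clipped to [0, 1], the
    number of clipped values, and the uncapped values for diagnostics.
    """
    raw = model.predict_raw(X_new)
    capped = np.clip(raw, 0.0, 1.0)
    n_capped = int(np.sum((raw < 0.0) | (raw > 1.0)))
    return capped, n_capped, raw
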