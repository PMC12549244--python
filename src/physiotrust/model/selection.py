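"""Two-round relaxed-LASSO stability selection.

Round 1: the LASSO path is cross-validated ``n_reps_round1`` times (fold
assignment re-randomized each repetition); each repetition records the
support at two penalty choices — the CV-MSE minimum and the one-standard-
error (1-SE) rule (the largest λ whose mean CV MSE is within one SE of the
minimum).  With the default 50 repetitions this yields 100 recorded
predictor sets, of which the unique ones are retained.

Round 2: the union of all round-1 features re-enters the same procedure for
``n_reps_round2`` repetitions at the 1-SE rule only, yielding the candidate
sets handed to the OLS refit ("relaxed" step).

The λ grid is logarithmic, auto-scaled from λ_max = max|X'y|/n of the
standardized data.  X is standardized internally for the penalty only;
candidate sets are feature-name sets, not coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

__all__ = ["SelectionConfig", "lasso_stability_select", "cv_lasso_support"]


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the stability-selection procedure.

    ``n_reps_round1``/``n_reps_round2`` default to the reference procedure's
    50; ``n_lambdas`` and the rep counts can be reduced for quick runs.
    """

    n_reps_round1: int = 50
    n_reps_round2: int = 50
    cv_folds: int = 10
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-2
    seed: int = 0

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if min(self.n_reps_round1, self.n_reps_round2) < 1:
            raise ValueError("repetition counts must be >= 1")


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 1e-12, sd, 1.0)
    return (X - mu) / sd_safe, sd > 1e-12


def _lambda_grid(Xs: np.ndarray, yc: np.ndarray, cfg: SelectionConfig) -> np.ndarray:
    n = Xs.shape[0]
    lam_max = np.max(np.abs(Xs.T @ yc)) / n
    if lam_max <= 0:
        raise ValueError("X carries no covariance with y; cannot scale the λ grid")
    return np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambdas)


def cv_lasso_support(
    Xs: np.ndarray,
    yc: np.ndarray,
    alphas: np.ndarray,
    coefs_full: np.ndarray,
    cfg: SelectionConfig,
    rng: np.random.Generator,
):
    """One repetition: K-fold CV over the λ grid; returns the support index
    arrays at (min-MSE λ, 1-SE λ)."""
    n = Xs.shape[0]
    kf = KFold(n_splits=cfg.cv_folds, shuffle=True,
               random_state=int(rng.integers(2**31 - 1)))
    mse = np.empty((cfg.cv_folds, alphas.size))
    for k, (tr, va) in enumerate(kf.split(Xs)):
        _, coefs, _ = lasso_path(Xs[tr], yc[tr], alphas=alphas)
        resid = yc[va][:, None] - Xs[va] @ coefs  # intercept handled by centering
        resid -= resid.mean(axis=0)  # fold-specific intercept offset
        mse[k] = np.mean(resid**2, axis=0)
    mean_mse = mse.mean(axis=0)
    se = mse.std(axis=0, ddof=1) / np.sqrt(cfg.cv_folds)
    i_min = int(np.argmin(mean_mse))
    thresh = mean_mse[i_min] + se[i_min]
    # largest λ within one SE: alphas descend, so the smallest index qualifying
    i_1se = int(np.flatnonzero(mean_mse <= thresh)[0])
    sup_min = np.flatnonzero(coefs_full[:, i_min] != 0)
    sup_1se = np.flatnonzero(coefs_full[:, i_1se] != 0)
    return sup_min, sup_1se


def lasso_stability_select(
    X: pd.DataFrame, y: pd.Series | np.ndarray, config: SelectionConfig | None = None
):
    """Run both selection rounds.

    Returns a dict with ``round1_sets`` (all recorded supports, up to
    2 x n_reps_round1 frozensets of column names), ``round1_unique``,
    ``round2_input`` (the union), and ``round2_sets`` (n_reps_round2
    supports at the 1-SE rule, possibly empty sets).
    """
    cfg = config or SelectionConfig()
    cols = np.asarray(X.columns)
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    n = Xv.shape[0]
    if n < cfg.cv_folds:
        raise ValueError(f"need at least cv_folds={cfg.cv_folds} observations, got {n}")
    if np.std(yv) < 1e-12:
        raise ValueError("y is constant; selection undefined")
    Xs, varying = _standardize(Xv)
    if not varying.any():
        raise ValueError("all columns of X are constant")
    Xs = Xs[:, varying]
    live_cols = cols[varying]
    yc = yv - yv.mean()
    Xs = np.asfortranarray(Xs)

    rng = np.random.default_rng(cfg.seed)
    alphas = _lambda_grid(Xs, yc, cfg)
    _, coefs_full, _ = lasso_path(Xs, yc, alphas=alphas)

    round1_sets: list[frozenset] = []
    for _ in range(cfg.n_reps_round1):
        sup_min, sup_1se = cv_lasso_support(Xs, yc, alphas, coefs_full, cfg, rng)
        round1_sets.append(frozenset(live_cols[sup_1se]))
        round1_sets.append(frozenset(live_cols[sup_min]))
    round1_unique = list(dict.fromkeys(round1_sets))

    union = sorted(set().union(*round1_unique)) if round1_unique else []
    if not union:
        return {
            "round1_sets": round1_sets,
            "round1_unique": round1_unique,
            "round2_input": [],
            "round2_sets": [frozenset()] * cfg.n_reps_round2,
        }

    keep = np.isin(live_cols, union)
    Xs2 = np.asfortranarray(Xs[:, keep])
    cols2 = live_cols[keep]
    alphas2 = _lambda_grid(Xs2, yc, cfg)
    _, coefs_full2, _ = lasso_path(Xs2, yc, alphas=alphas2)
    round2_sets = []
    for _ in range(cfg.n_reps_round2):
        _, sup_1se = cv_lasso_support(Xs2, yc, alphas2, coefs_full2, cfg, rng)
        round2_sets.append(frozenset(cols2[sup_1se]))

    return {
        "round1_sets": round1_sets,
        "round1_unique": round1_unique,
        "round2_input": union,
        "round2_sets": round2_sets,
    }
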