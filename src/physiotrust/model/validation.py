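"""Candidate evaluation: exhaustive leave-one-trial-out Q², anti-overfitting
constraints, and final model choice.

LOTO Q² refits the candidate's OLS on all trials but one, predicts the
held-out trial's epochs (capped to the [0, 1] trust scale), and aggregates
PRESS over all trials: Q² = 1 - PRESS / TSS with TSS about the fitting
partition's mean.  The refits reuse the full Gram matrix, downdated by each
trial's block, so the sweep costs one p x p solve per trial.

Final selection applies the two overfitting guards — at most n/5 predictors,
and LOTO Q² within 0.2 of the adjusted R² — then takes the surviving
candidate with the highest adjusted R² (ties: fewer predictors, then
lexicographic order).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from physiotrust.model.regression import CandidateModel, fit_ols

__all__ = ["loto_q2", "build_candidates", "select_model", "ModelSelectionError"]

MAX_PRED_FRACTION = 1.0 / 5.0
Q2_GAP_LIMIT = 0.2


class ModelSelectionError(RuntimeError):
    pass


def loto_q2(X: pd.DataFrame, y, trial_ids, predictors, cap: bool = True) -> float:
    """Exhaustive leave-one-trial-out predictive R² for one predictor set.

    ``trial_ids`` labels each row's trial (any hashable per-row label); with
    T trials, each sub-fit uses T - 1 trials.  Predictions are capped to
    [0, 1] before scoring (matching the deployment rule).
    """
    predictors = list(predictors)
    missing = [c for c in predictors if c not in X.columns]
    if missing:
        raise KeyError(f"predictors absent from matrix: {missing[:5]}")
    yv = np.asarray(y, dtype=float)
    codes = pd.factorize(pd.Series(trial_ids, dtype="object"))[0]
    n_trials = codes.max() + 1
    if n_trials < 2:
        raise ValueError("LOTO needs at least 2 trials")

    # resolve exact collinearity once, on the full fitting partition
    base = fit_ols(X, yv, predictors)
    cols = list(base.predictors)
    D = np.column_stack([np.ones(len(yv)), np.asarray(X[cols], dtype=float)])
    G = D.T @ D
    b = D.T @ yv

    press = 0.0
    for t in range(n_trials):
        m = codes == t
        Dt, yt = D[m], yv[m]
        Gt = G - Dt.T @ Dt
        bt = b - Dt.T @ yt
        try:
            beta = np.linalg.solve(Gt, bt)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(Gt, bt, rcond=None)
        pred = Dt @ beta
        if cap:
            pred = np.clip(pred, 0.0, 1.0)
        press += float(np.sum((yt - pred) ** 2))

    tss = float(np.sum((yv - yv.mean()) ** 2))
    if tss <= 0:
        raise ValueError("constant y; Q² undefined")
    return 1.0 - press / tss


def build_candidates(
    X: pd.DataFrame, y, trial_ids, predictor_sets
) -> list[CandidateModel]:
    """OLS-refit and LOTO-score each unique predictor set."""
    out = []
    seen = set()
    n = len(X)
    for s in predictor_sets:
        key = frozenset(s)
        if key in seen:
            continue
        seen.add(key)
        if len(key) >= n - 1:
            # unfittable at this sample size; the n/5 constraint would
            # eliminate it anyway
            continue
        preds = sorted(key)
        model = fit_ols(X, y, preds)
        model.loto_q2 = loto_q2(X, y, trial_ids, model.predictors)
        out.append(model)
    return out


def select_model(candidates, n_obs: int) -> CandidateModel:
    """Apply the overfitting constraints and pick the best survivor."""
    if not candidates:
        raise ModelSelectionError("no candidate models supplied")
    limit = n_obs * MAX_PRED_FRACTION
    survivors = []
    for m in candidates:
        if m.p > limit:
            continue
        if not np.isfinite(m.adj_r2) or not np.isfinite(m.loto_q2):
            continue
        if abs(m.adj_r2 - m.loto_q2) > Q2_GAP_LIMIT:
            continue
        survivors.append(m)
    if not survivors:
        raise ModelSelectionError(
            f"all {len(candidates)} candidates eliminated by the constraints "
            f"(p <= {limit:.0f}, |adjR² - Q²| <= {Q2_GAP_LIMIT}); consider more data "
            "or a different selection configuration"
        )
    survivors.sort(key=lambda m: (-m.adj_r2, m.p, m.predictors))
    return survivors[0]
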