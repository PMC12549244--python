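"""Monte-Carlo cross-validation over LOTOPS splits, and the descriptive
(all-data) model.

Each split: the versioned design matrix is expanded with participant
statistics from training epochs only, stability selection and candidate
building run on the training partition, the constrained best candidate is
selected, and test metrics (test Q², RMSE, median absolute error, capped
count) are computed on the withheld trials.  The whole procedure repeats
``n_splits`` times (default 10) with fresh random splits.

MAE here is the MEDIAN absolute error, not the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from physiotrust.features.dictionary import FEATURE_DICTIONARY, CATEGORY_FEATURES
from physiotrust.features.matrix import FeatureMatrix
from physiotrust.model import (
    SelectionConfig,
    build_candidates,
    lasso_stability_select,
    predict_trust,
    select_model,
)

__all__ = [
    "Metrics",
    "compute_metrics",
    "run_single_split",
    "run_mccv",
    "fit_descriptive",
    "MccvReport",
]


@dataclass(frozen=True)
class Metrics:
    rmse: float
    mae: float          # median absolute error
    q2: float
    n_capped: int = 0


def compute_metrics(y_true, y_pred, train_mean: float | None = None, n_capped: int = 0) -> Metrics:
    """RMSE, median absolute error and predictive Q².

    ``train_mean`` anchors the Q² denominator at the fitting partition's
    mean trust; defaults to the mean of ``y_true``.
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.size == 0 or yt.size != yp.size:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    err = yt - yp
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.median(np.abs(err)))
    ref = float(np.mean(yt)) if train_mean is None else float(train_mean)
    tss = float(np.sum((yt - ref) ** 2))
    q2 = 1.0 - float(np.sum(err**2)) / tss if tss > 0 else np.nan
    return Metrics(rmse=rmse, mae=mae, q2=q2, n_capped=n_capped)


@dataclass
class MccvReport:
    """Per-split rows plus mean/SD summary, Table-2-style."""

    table: pd.DataFrame          # one row per split
    summary: pd.DataFrame        # 'mean' and 'sd' rows
    models: list                 # selected CandidateModel per split
    per_participant_rmse: pd.Series | None = None
    detail_split: int | None = None


def _trial_labels(keys: pd.DataFrame) -> pd.Series:
    return (
        keys["participant"].astype(str)
        + "-" + keys["session"].astype(str)
        + "-" + keys["trial"].astype(str)
    )


def run_single_split(
    matrix: FeatureMatrix,
    scheme,
    config: SelectionConfig,
):
    """Feature selection + fit on training epochs, evaluation on withheld
    trials.  Returns ``(model, row_dict, detail)``."""
    keys = matrix.keys
    test_mask = scheme.is_test(keys)
    train_idx = matrix.base.index[~test_mask]
    test_idx = matrix.base.index[test_mask]

    X, y = matrix.versioned(train_index=train_idx)
    X_tr, y_tr = X.loc[train_idx], y.loc[train_idx]
    X_te, y_te = X.loc[test_idx], y.loc[test_idx]
    trials_tr = _trial_labels(keys.loc[train_idx])

    sel = lasso_stability_select(X_tr, y_tr, config)
    candidates = build_candidates(X_tr, y_tr, trials_tr, sel["round2_sets"])
    model = select_model(candidates, n_obs=len(train_idx))

    pred, n_capped, _ = predict_trust(model, X_te)
    m = compute_metrics(y_te, pred, train_mean=float(np.mean(y_tr)), n_capped=n_capped)
    row = {
        "adj_r2": model.adj_r2,
        "model_q2": model.loto_q2,
        "test_q2": m.q2,
        "rmse": m.rmse,
        "mae": m.mae,
        "predictors": model.p,
        "capped": n_capped,
    }
    detail = {
        "test_index": test_idx,
        "y_test": np.asarray(y_te, dtype=float),
        "y_pred": pred,
        "selection": sel,
    }
    return model, row, detail


def run_mccv(
    matrix: FeatureMatrix,
    config: SelectionConfig | None = None,
    n_splits: int = 10,
    seed: int = 0,
    detail_split: int | None = None,
) -> MccvReport:
    """Repeat the LOTOPS split + selection + evaluation ``n_splits`` times.

    ``detail_split`` (1-based) picks the split whose per-participant RMSE
    table and traces are retained; defaults to the last split.
    """
    from physiotrust.evaluate.splits import lotops_split

    cfg = config or SelectionConfig()
    if detail_split is None:
        detail_split = n_splits
    design = _design_from_keys(matrix.keys)

    rows, models = [], []
    per_participant = None
    detail_out = None
    for i in range(n_splits):
        scheme = lotops_split(design, seed=seed * 1000 + i)
        split_cfg = SelectionConfig(
            n_reps_round1=cfg.n_reps_round1,
            n_reps_round2=cfg.n_reps_round2,
            cv_folds=cfg.cv_folds,
            n_lambdas=cfg.n_lambdas,
            lambda_min_ratio=cfg.lambda_min_ratio,
            seed=cfg.seed * 1000 + i,
        )
        try:
            model, row, detail = run_single_split(matrix, scheme, split_cfg)
        except Exception as exc:
            raise RuntimeError(f"MCCV split {i + 1} failed: {exc}") from exc
        row["split"] = i + 1
        rows.append(row)
        models.append(model)
        if i + 1 == detail_split:
            keys_te = matrix.keys.loc[detail["test_index"]]
            err = pd.Series(
                (detail["y_test"] - detail["y_pred"]) ** 2,
                index=keys_te["participant"].to_numpy(),
            )
            per_participant = err.groupby(level=0).mean().pow(0.5)
            per_participant.name = "rmse"
            detail_out = detail

    table = pd.DataFrame(rows).set_index("split")
    summary = pd.DataFrame(
        {"mean": table.mean(axis=0), "sd": table.std(axis=0, ddof=1)}
    ).T
    return MccvReport(
        table=table,
        summary=summary,
        models=models,
        per_participant_rmse=per_participant,
        detail_split=detail_split,
    )


def _design_from_keys(keys: pd.DataFrame):
    from physiotrust.design import StudyDesign

    return StudyDesign(
        n_participants=int(keys["participant"].max()),
        n_sessions=int(keys["session"].max()),
        n_trials=int(keys["trial"].max()),
        n_epochs=int(keys["epoch"].max()),
    )


def fit_descriptive(matrix: FeatureMatrix, config: SelectionConfig | None = None):
    """The 'overall' model on 100% of the epochs.

    Returns ``(model, stats, retention)``: overall fit statistics and the
    per-category created/retained feature counts.
    """
    cfg = config or SelectionConfig()
    X, y = matrix.versioned(train_index=None)
    trials = _trial_labels(matrix.keys)
    sel = lasso_stability_select(X, y, cfg)
    candidates = build_candidates(X, y, trials, sel["round2_sets"])
    model = select_model(candidates, n_obs=len(X))

    pred, n_capped, _ = predict_trust(model, X)
    m = compute_metrics(y, pred, train_mean=float(np.mean(y)), n_capped=n_capped)
    stats = {
        "adj_r2": model.adj_r2,
        "rmse": m.rmse,
        "mae": m.mae,
        "predictors": model.p,
        "capped": n_capped,
    }

    # "created" counts base features per category (the dictionary's counts);
    # "retained" counts selected design-matrix columns mapped to the category
    created, retained = {}, {}
    for cat, names in CATEGORY_FEATURES.items():
        created[cat] = len(names)
        retained[cat] = sum(
            1 for c in model.predictors if FEATURE_DICTIONARY.base_of(c) in names
        )
    retention = pd.DataFrame(
        {"created": pd.Series(created), "retained": pd.Series(retained)}
    )
    retention["pct_retained"] = 100.0 * retention["retained"] / retention["created"]
    assert retention["retained"].sum() == model.p
    return model, stats, retention
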