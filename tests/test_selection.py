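"""Stability-selection behavior: planted-predictor retention, null-data
sparsity, recorded set counts and the 1-SE/min-MSE monotonicity."""

import numpy as np
import pandas as pd
import pytest

from physiotrust.model import SelectionConfig, lasso_stability_select
from physiotrust.model.selection import _lambda_grid, _standardize, cv_lasso_support
from sklearn.linear_model import lasso_path


def _planted_instance(n=500, p_noise=200, effect=1.0, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.standard_normal((n, p_noise + 1)),
        columns=["planted"] + [f"n{i}" for i in range(p_noise)],
    )
    y = effect * X["planted"].to_numpy() + rng.standard_normal(n)
    return X, y


def test_planted_predictor_survives_both_rounds():
    X, y = _planted_instance()
    cfg = SelectionConfig(n_reps_round1=10, n_reps_round2=10, n_lambdas=40, seed=1)
    sel = lasso_stability_select(X, y, cfg)
    hits = sum("planted" in s for s in sel["round2_sets"])
    assert hits >= 0.9 * len(sel["round2_sets"])


def test_null_data_yields_sparse_round2_sets():
    sizes = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.standard_normal((200, 50)),
                         columns=[f"n{i}" for i in range(50)])
        y = rng.standard_normal(200)
        cfg = SelectionConfig(n_reps_round1=2, n_reps_round2=2, n_lambdas=30,
                              cv_folds=5, seed=seed)
        try:
            sel = lasso_stability_select(X, y, cfg)
        except ValueError:
            sizes.append(0)  # no covariance with y at all
            continue
        sizes.extend(len(s) for s in sel["round2_sets"])
    assert np.median(sizes) <= 2


def test_recorded_round1_set_count_is_two_per_rep():
    X, y = _planted_instance(n=120, p_noise=10)
    cfg = SelectionConfig(n_reps_round1=50, n_reps_round2=1, n_lambdas=25,
                          cv_folds=5, seed=0)
    sel = lasso_stability_select(X, y, cfg)
    assert len(sel["round1_sets"]) == 100  # 50 reps x {1-SE, min-MSE}


def test_one_se_support_never_larger_than_min_mse_support():
    X, y = _planted_instance(n=300, p_noise=60, effect=0.5, seed=3)
    cfg = SelectionConfig(n_lambdas=40, cv_folds=5, seed=3)
    Xs, varying = _standardize(np.asarray(X, dtype=float))
    yc = np.asarray(y) - np.mean(y)
    alphas = _lambda_grid(Xs, yc, cfg)
    _, coefs_full, _ = lasso_path(np.asfortranarray(Xs), yc, alphas=alphas)
    rng = np.random.default_rng(0)
    for _ in range(5):
        sup_min, sup_1se = cv_lasso_support(Xs, yc, alphas, coefs_full, cfg, rng)
        assert len(sup_1se) <= len(sup_min)


def test_round2_input_is_union_of_round1_sets():
    X, y = _planted_instance(n=200, p_noise=30, seed=5)
    cfg = SelectionConfig(n_reps_round1=5, n_reps_round2=3, n_lambdas=25,
                          cv_folds=5, seed=5)
    sel = lasso_stability_select(X, y, cfg)
    union = set().union(*sel["round1_unique"])
    assert set(sel["round2_input"]) == union
    for s in sel["round2_sets"]:
        assert s <= union


def test_constant_y_rejected():
    X, _ = _planted_instance(n=50, p_noise=5)
    with pytest.raises(ValueError, match="constant"):
        lasso_stability_select(X, np.ones(50), SelectionConfig(cv_folds=5))


def test_all_constant_x_rejected():
    X = pd.DataFrame(np.ones((50, 4)), columns=list("abcd"))
    y = np.random.default_rng(0).standard_normal(50)
    with pytest.raises(ValueError):
        lasso_stability_select(X, y, SelectionConfig(cv_folds=5))
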