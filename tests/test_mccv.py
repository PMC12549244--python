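"""MCCV harness behavior on a feature-level synthetic matrix (fast: no
waveform synthesis), including the label-permutation leakage canary."""

import numpy as np
import pandas as pd
import pytest

from physiotrust import SelectionConfig, predict_trust
from physiotrust.evaluate import fit_descriptive, run_mccv, run_single_split, lotops_split
from physiotrust.evaluate.mccv import _design_from_keys
from physiotrust.features.dictionary import CATEGORY_FEATURES

from conftest import make_feature_level_matrix

CFG = SelectionConfig(n_reps_round1=4, n_reps_round2=4, cv_folds=5, n_lambdas=20,
                      lambda_min_ratio=3e-2, seed=0)


@pytest.fixture(scope="module")
def mccv_report(feature_level_matrix):
    fm, _ = feature_level_matrix
    return run_mccv(fm, CFG, n_splits=3, seed=1)


def test_report_has_one_row_per_split(mccv_report):
    assert len(mccv_report.table) == 3
    assert list(mccv_report.table.columns) == [
        "adj_r2", "model_q2", "test_q2", "rmse", "mae", "predictors", "capped"
    ]


def test_summary_row_is_mean_of_split_rows(mccv_report):
    assert np.allclose(
        mccv_report.summary.loc["mean"].to_numpy(),
        mccv_report.table.mean(axis=0).to_numpy(),
        atol=1e-12,
    )
    assert np.allclose(
        mccv_report.summary.loc["sd"].to_numpy(),
        mccv_report.table.std(axis=0, ddof=1).to_numpy(),
        atol=1e-12,
    )


def test_high_signal_data_positive_test_q2(mccv_report):
    assert (mccv_report.table["test_q2"] > 0).all()


def test_per_participant_rmse_table(mccv_report):
    rmse = mccv_report.per_participant_rmse
    assert rmse is not None
    assert len(rmse) == 4  # every participant contributes test data
    assert (rmse >= 0).all()


def test_leakage_canary_label_permutation(feature_level_matrix):
    """Permuting the withheld trials' trust labels must destroy test Q²."""
    fm, _ = feature_level_matrix
    design = _design_from_keys(fm.keys)
    scheme = lotops_split(design, seed=5)
    model, row, detail = run_single_split(fm, scheme, CFG)
    assert row["test_q2"] > 0.3
    rng = np.random.default_rng(0)
    y_perm = rng.permutation(detail["y_test"])
    ss_res = np.sum((y_perm - detail["y_pred"]) ** 2)
    ss_tot = np.sum((detail["y_test"] - detail["y_test"].mean()) ** 2)
    q2_perm = 1 - ss_res / ss_tot
    assert q2_perm <= 0.1


def test_descriptive_model_retention_partition(feature_level_matrix):
    fm, _ = feature_level_matrix
    model, stats, retention = fit_descriptive(fm, CFG)
    assert set(retention.index) == set(CATEGORY_FEATURES)
    assert retention["retained"].sum() == model.p
    assert retention["created"].sum() == 682
    assert stats["adj_r2"] == pytest.approx(model.adj_r2)


def test_descriptive_noiseless_planted_data_near_perfect():
    # signal carried by embedded measures, which enter unversioned, so the
    # noiseless mapping is exactly linear in the design matrix
    fm, cols = make_feature_level_matrix(
        n_participants=2, n_sessions=2, n_trials=4, n_epochs=6,
        noise_sd=0.0, signal_strength=0.05, seed=3, n_signal=4,
        signal_from="emb",
    )
    model, stats, _ = fit_descriptive(
        fm, SelectionConfig(n_reps_round1=3, n_reps_round2=3, cv_folds=5,
                            n_lambdas=20, lambda_min_ratio=3e-2, seed=3)
    )
    assert stats["adj_r2"] >= 0.99


def test_predictions_bounded_in_unit_interval(mccv_report, feature_level_matrix):
    fm, _ = feature_level_matrix
    X, _ = fm.versioned()
    for model in mccv_report.models:
        capped, _, _ = predict_trust(model, X)
        assert capped.min() >= 0.0 and capped.max() <= 1.0
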