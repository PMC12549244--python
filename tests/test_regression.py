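"""OLS refit: equivalence with the normal-equations oracle, the adjusted-R²
formula, collinearity handling and bounded prediction."""

import numpy as np
import pandas as pd
import pytest

from physiotrust.model import CandidateModel, fit_ols, predict_trust


def _random_instance(rng, n, p):
    X = pd.DataFrame(
        rng.standard_normal((n, p)), columns=[f"x{i}" for i in range(p)]
    )
    beta = rng.standard_normal(p)
    y = 0.3 + X.to_numpy() @ beta + 0.1 * rng.standard_normal(n)
    return X, y


@pytest.mark.parametrize("seed", range(8))
def test_ols_matches_normal_equations_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(12, 51))
    p = int(rng.integers(1, 6))
    X, y = _random_instance(rng, n, p)
    m = fit_ols(X, y)
    # brute-force normal equations
    D = np.column_stack([np.ones(n), X.to_numpy()])
    beta_oracle = np.linalg.solve(D.T @ D, D.T @ y)
    assert m.intercept == pytest.approx(beta_oracle[0], abs=1e-8)
    assert np.allclose(m.coef, beta_oracle[1:], atol=1e-8)


def test_exact_linear_data_perfect_fit():
    rng = np.random.default_rng(1)
    X = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
    y = 1.0 + X["a"] - 2 * X["b"] + 0.5 * X["c"]
    m = fit_ols(X, y)
    assert m.r2 == pytest.approx(1.0, abs=1e-12)
    resid = y - m.predict_raw(X)
    assert np.max(np.abs(resid)) < 1e-10


def test_adjusted_r2_formula():
    # n=10, p=2, R²=0.5 -> adj = 1 - 0.5 * 9/7
    adj = 1.0 - (1.0 - 0.5) * (10 - 1) / (10 - 2 - 1)
    assert adj == pytest.approx(0.35714285, abs=1e-6)
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "b"])
    y = X["a"] + 2.0 * rng.standard_normal(10)
    m = fit_ols(X, y)
    expect = 1.0 - (1.0 - m.r2) * 9 / 7
    assert m.adj_r2 == pytest.approx(expect, abs=1e-12)


def test_duplicate_column_dropped_with_warning():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.standard_normal((20, 2)), columns=["a", "b"])
    X["a_copy"] = X["a"]
    y = X["a"] + 0.1 * rng.standard_normal(20)
    with pytest.warns(UserWarning, match="collinear"):
        m = fit_ols(X, y)
    assert len(m.dropped) == 1
    assert m.p == 2


def test_n_too_small_rejected():
    X = pd.DataFrame(np.ones((3, 3)), columns=list("abc"))
    with pytest.raises(ValueError, match="n > p"):
        fit_ols(X, np.ones(3))


class TestPredictTrust:
    def _model(self):
        return CandidateModel(
            predictors=("x",), coef=np.array([1.0]), intercept=0.0,
            r2=1.0, adj_r2=1.0, n_obs=10,
        )

    def test_capping_above_and_below(self):
        m = self._model()
        X = pd.DataFrame({"x": [1.3, -0.2, 0.5]})
        capped, n_capped, raw = predict_trust(m, X)
        assert np.allclose(capped, [1.0, 0.0, 0.5])
        assert n_capped == 2
        assert np.allclose(raw, [1.3, -0.2, 0.5])  # uncapped recoverable

    def test_missing_predictor_column_rejected(self):
        m = self._model()
        with pytest.raises(KeyError):
            predict_trust(m, pd.DataFrame({"z": [0.1]}))

    def test_roundtrip_serialization(self):
        m = self._model()
        m2 = CandidateModel.from_dict(m.to_dict())
        assert m2.predictors == m.predictors
        assert np.allclose(m2.coef, m.coef)
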