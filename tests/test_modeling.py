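"""Stepwise selection, PLS regression and the fitted-model container."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gqsar.dataset import autoscale
from gqsar.errors import ConfigError, DataError
from gqsar.modeling import (FittedModel, SelectionConfig, choose_components,
                            contributions, finalize, fit_pls, partial_f,
                            stepwise_forward)


# ---------------------------------------------------------------- partial F
def test_partial_f_hand_values():
    assert partial_f(10.0, 10.0, n=10, p_full=1) == 0.0
    assert partial_f(10.0, 5.0, n=10, p_full=1) == pytest.approx(8.0)
    assert partial_f(10.0, 0.0, n=10, p_full=1) == math.inf
    with pytest.raises(DataError):
        partial_f(10.0, 5.0, n=3, p_full=2)


def test_selection_config_invariants():
    with pytest.raises(ConfigError):
        SelectionConfig(f_to_enter=3.0, f_to_remove=4.0)
    with pytest.raises(ConfigError):
        SelectionConfig(cross_correlation_limit=0.0)
    assert SelectionConfig().resolved_max_terms(26) == 5


# ---------------------------------------------------------------- stepwise
def _planted_frame(seed, n=40, sigma=0.05, k_noise=10):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, k_noise + 2)),
                     columns=[f"d{i}" for i in range(1, k_noise + 3)])
    y = 2.0 * X["d1"] - X["d2"] + rng.normal(0, sigma, n)
    return X, y


def test_stepwise_recovers_planted_two_term_model():
    X, y = _planted_frame(seed=3)
    selected, trace = stepwise_forward(X, y)
    assert sorted(selected) == ["d1", "d2"]
    assert any("enter d1" in t for t in trace)


def test_stepwise_identical_columns_tie_break_is_lexicographic():
    rng = np.random.default_rng(0)
    base = rng.normal(size=30)
    X = pd.DataFrame({"b_dup": base, "a_dup": base,
                      "noise": rng.normal(size=30)})
    y = base + rng.normal(0, 0.05, 30)
    selected, _ = stepwise_forward(X, y)
    assert selected[0] == "a_dup"          # lexicographic winner
    assert "b_dup" not in selected         # perfect correlation cap


def test_stepwise_invariant_to_column_order():
    X, y = _planted_frame(seed=5)
    s1, _ = stepwise_forward(X, y)
    s2, _ = stepwise_forward(X[list(reversed(X.columns))], y)
    assert s1 == s2


def test_stepwise_rejects_degenerate_input():
    X, y = _planted_frame(seed=1)
    X = X.assign(dead=1.0)
    with pytest.raises(DataError, match="zero-variance"):
        stepwise_forward(X, y)
    with pytest.raises(DataError):
        stepwise_forward(X.iloc[:4, :2], y[:4])


# -------------------------------------------------------------------- PLS
def test_pls_single_descriptor_equals_univariate_slope():
    rng = np.random.default_rng(2)
    x = rng.normal(size=25)
    y = 1.7 * x + rng.normal(0, 0.1, 25)
    xc, yc = x - x.mean(), y - y.mean()
    model = fit_pls(xc.reshape(-1, 1), yc, 1)
    slope = float(xc @ yc / (xc @ xc))
    assert model.coef_[0] == pytest.approx(slope, abs=1e-12)


def test_pls_full_rank_equals_least_squares():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(20, 3))
    y = rng.normal(size=20)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    model = fit_pls(Xc, yc, 3)
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)   # normal-equations oracle
    assert np.allclose(model.coef_, beta, atol=1e-8)


def test_pls_matches_sklearn_reference():
    sklearn = pytest.importorskip("sklearn.cross_decomposition")
    rng = np.random.default_rng(11)
    X = rng.normal(size=(30, 5))
    y = X @ np.array([1.0, -0.5, 0.2, 0.0, 0.0]) + rng.normal(0, 0.2, 30)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    for nc in (1, 2, 3):
        ours = fit_pls(Xc, yc, nc)
        ref = sklearn.PLSRegression(n_components=nc, scale=False).fit(Xc, yc)
        assert np.allclose(ours.coef_, ref.coef_.ravel(), atol=1e-8)


def test_pls_zero_variance_response_gives_zero_vector():
    X = np.random.default_rng(0).normal(size=(10, 2))
    model = fit_pls(X - X.mean(axis=0), np.zeros(10), 2)
    assert np.allclose(model.coef_, 0.0)
    assert model.n_components == 0


def test_pls_component_bounds():
    X = np.zeros((6, 2))
    with pytest.raises(ConfigError):
        fit_pls(X, np.zeros(6), 5)


# ------------------------------------------------------------- components
def test_choose_components_noiseless_two_descriptors():
    rng = np.random.default_rng(4)
    X = pd.DataFrame({"a": rng.normal(size=24), "b": rng.normal(size=24)})
    y = 1.0 * X["a"] - 2.0 * X["b"]
    assert choose_components(X, y) == 2


def test_choose_components_single_descriptor():
    rng = np.random.default_rng(4)
    X = pd.DataFrame({"a": rng.normal(size=12)})
    assert choose_components(X, 0.5 * X["a"]) == 1


# ---------------------------------------------------------------- finalize
def _toy_fit(seed=0, n=30):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"a": rng.normal(2, 3, n), "b": rng.normal(-1, 0.5, n)})
    y = 0.8 * X["a"] - 2.0 * X["b"] + 5 + rng.normal(0, 0.1, n)
    X_scaled, means, sds = autoscale(X)
    pls = fit_pls(X_scaled.to_numpy(), y - y.mean(), 2)
    fitted = finalize(pls, X, y, means, sds)
    return X, y, X_scaled, pls, fitted


def test_finalize_backtransform_preserves_predictions():
    X, y, X_scaled, pls, fitted = _toy_fit()
    scaled_pred = pls.predict(X_scaled.to_numpy()) + y.mean()
    assert np.allclose(fitted.predict(X), scaled_pred, atol=1e-8)


def test_finalize_identity_scaling_keeps_coefficients():
    X, y, X_scaled, pls, _ = _toy_fit()
    ident_mean = pd.Series(0.0, index=X.columns)
    ident_sd = pd.Series(1.0, index=X.columns)
    fitted = finalize(pls, X_scaled, y, ident_mean, ident_sd)
    assert np.allclose(fitted.coefficients, pls.coef_)


def test_fitted_model_roundtrips_exactly(tmp_path):
    *_, fitted = _toy_fit(seed=9)
    path = tmp_path / "model.json"
    fitted.save(path)
    back = FittedModel.load(path)
    assert back.descriptor_names == fitted.descriptor_names
    assert np.array_equal(back.coefficients, fitted.coefficients)
    assert back.intercept == fitted.intercept
    assert back.scaling == fitted.scaling
    assert back.training_ranges == fitted.training_ranges


def test_equation_rendering_mentions_every_term():
    *_, fitted = _toy_fit()
    eq = fitted.equation()
    assert eq.startswith("pIC50 = ")
    for name in fitted.descriptor_names:
        assert name in eq


# ----------------------------------------------------------------- predict
def test_predict_flags_out_of_range_inputs():
    *_, fitted = _toy_fit()
    lo, hi = fitted.training_ranges["a"]
    inside = {"a": (lo + hi) / 2, "b": sum(fitted.training_ranges["b"]) / 2}
    _, flag = fitted.predict_one(inside)
    assert flag is False
    outside = dict(inside, a=hi + 10)
    _, flag = fitted.predict_one(outside)
    assert flag is True
    with pytest.raises(DataError, match="missing"):
        fitted.predict_one({"a": 0.0})


@given(st.floats(-5, 5), st.floats(-5, 5), st.floats(0, 1))
@settings(max_examples=50, deadline=None)
def test_predict_is_affine(v1, v2, alpha):
    *_, fitted = _toy_fit()
    d1 = {"a": v1, "b": v2}
    d2 = {"a": v2, "b": v1}
    mix = {k: alpha * d1[k] + (1 - alpha) * d2[k] for k in d1}
    p1, _ = fitted.predict_one(d1)
    p2, _ = fitted.predict_one(d2)
    pm, _ = fitted.predict_one(mix)
    assert pm == pytest.approx(alpha * p1 + (1 - alpha) * p2, abs=1e-9)


# ------------------------------------------------------------ contributions
def test_contribution_percentages():
    def model_with_scaled(scaled):
        names = [f"d{i}" for i in range(len(scaled))]
        return FittedModel(
            descriptor_names=names,
            coefficients=np.array(scaled, dtype=float),  # sd=1 ⇒ scaled=orig
            intercept=0.0, n_components=1,
            scaling={n: (0.0, 1.0) for n in names},
            training_ranges={n: (-1, 1) for n in names})

    assert contributions(model_with_scaled([3.0])).tolist() == [100.0]
    assert contributions(model_with_scaled([1.0, -1.0])).tolist() == [50.0, 50.0]
    assert contributions(model_with_scaled([2.0, 1.0, 1.0])).tolist() == [50.0, 25.0, 25.0]
    with pytest.raises(DataError):
        contributions(model_with_scaled([0.0, 0.0]))
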