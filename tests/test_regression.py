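"""MLR fitting and the validation suite against independent oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from mpqsar import (
    LinearGenSpec,
    MLRModel,
    fit_mlr,
    gen_linear,
    stepwise_select,
    vif,
)
from mpqsar.regression import SingularDesignError


def test_noiseless_data_recovered_exactly():
    X, y, truth = gen_linear(
        LinearGenSpec(n=40, k=3, intercept=2.0, beta=(3.0, -1.0, 0.5),
                      sigma=0.0, seed=3)
    )
    res = fit_mlr(X, y)
    assert res.rsquared == pytest.approx(1.0, abs=1e-12)
    assert res.rmse == pytest.approx(0.0, abs=1e-8)
    assert res.params["const"] == pytest.approx(2.0, abs=1e-8)
    assert res.params["x1"] == pytest.approx(3.0, abs=1e-8)
    assert res.q2_loo() == pytest.approx(1.0, abs=1e-8)


def test_constant_response_degenerate_convention(rng):
    X = pd.DataFrame({"x1": rng.normal(size=20)})
    res = fit_mlr(X, np.full(20, 5.0))
    assert res.degenerate
    assert res.rsquared == 0.0
    assert np.isnan(res.fvalue)


def test_singular_design_raises(rng):
    x = rng.normal(size=30)
    X = pd.DataFrame({"a": x, "b": 2 * x})
    with pytest.raises(SingularDesignError):
        MLRModel(rng.normal(size=30), X).fit()


def test_coefficient_recovery_within_standard_errors():
    X, y, truth = gen_linear(
        LinearGenSpec(n=200, k=2, intercept=2.0, beta=(3.0, -1.0),
                      sigma=1.0, seed=11)
    )
    res = fit_mlr(X, y)
    for name, true in [("const", 2.0), ("x1", 3.0), ("x2", -1.0)]:
        assert abs(res.params[name] - true) < 3 * res.bse[name]


def test_residuals_orthogonal_to_design(rng):
    X, y, _ = gen_linear(LinearGenSpec(n=60, k=4, sigma=2.0, seed=5))
    res = fit_mlr(X, y)
    for col in X.columns:
        assert abs(res.resid @ X[col].to_numpy()) < 1e-8
    assert abs(res.resid.sum()) < 1e-8


def test_press_shortcut_equals_literal_loo_refits():
    for seed in range(20):
        spec = LinearGenSpec(n=25, k=3, beta=(1.0, 0.5, -2.0),
                             sigma=1.5, seed=seed)
        X, y, _ = gen_linear(spec)
        res = fit_mlr(X, y)
        Xc = sm.add_constant(X).to_numpy()
        press = 0.0
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            b = np.linalg.lstsq(Xc[keep], y[keep], rcond=None)[0]
            press += (y[i] - Xc[i] @ b) ** 2
        assert res.press == pytest.approx(press, abs=1e-10 * max(1, press))


def test_q2_loo_below_r2_and_negative_under_null(rng):
    # fit always beats hold-out on the same data; pure noise gives Q2 <= 0
    q2s = []
    for seed in range(30):
        X, y, _ = gen_linear(LinearGenSpec(n=100, k=4, beta=(0,) * 4,
                                           sigma=1.0, seed=seed))
        res = fit_mlr(X, y)
        assert res.q2_loo() <= res.rsquared
        q2s.append(res.q2_loo())
    assert np.mean(q2s) < 0


def test_vif_orthogonal_duplicate_and_oracle(rng):
    n = 500
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
    v = vif(X)
    assert (v < 1.1).all()  # near-orthogonal random columns
    Xd = X.copy()
    Xd["d"] = X["a"]
    assert np.isinf(vif(Xd)["d"])
    # correlated design vs statsmodels' implementation
    Xcorr = X.copy()
    Xcorr["b"] = 0.8 * X["a"] + 0.6 * rng.normal(size=n)
    ours = vif(Xcorr)
    Xc = sm.add_constant(Xcorr).to_numpy()
    for j, col in enumerate(Xcorr.columns, start=1):
        assert ours[col] == pytest.approx(
            variance_inflation_factor(Xc, j), rel=1e-8
        )
    with pytest.raises(ValueError):
        vif(X[["a"]])


def test_q2_ext_trivial_identities():
    X, y, _ = gen_linear(LinearGenSpec(n=30, k=2, beta=(1.0, 2.0),
                                       sigma=0.0, seed=9))
    res = fit_mlr(X, y)
    rep = res.validate(X, y)
    assert rep.q2_ext == pytest.approx(1.0, abs=1e-10)
    assert rep.r2_ext == pytest.approx(1.0, abs=1e-10)
    # predictions identical to the training mean give Q2_ext = 0
    Xv = pd.DataFrame({"x1": [0.0, 0.0], "x2": [0.0, 0.0]})
    res2 = fit_mlr(X - X.mean(), y)  # centred: prediction at 0 = ybar
    rep2 = res2.validate(Xv, np.array([y.min(), y.max()]))
    # reference deviance uses the training mean
    expect = 1 - (((y.mean() - y.min()) ** 2 + (y.mean() - y.max()) ** 2)
                  / (((np.array([y.min(), y.max()]) - y.mean()) ** 2).sum()))
    assert rep2.q2_ext == pytest.approx(expect, abs=1e-10)
    with pytest.raises(ValueError):
        res.validate(X.iloc[:0], np.array([]))


def test_q2_ext_f2_variant_and_zero_variance_flag():
    X, y, _ = gen_linear(LinearGenSpec(n=30, k=2, sigma=0.5, seed=2))
    res = fit_mlr(X, y)
    f1 = res.validate(X.iloc[:5], y[:5], variant="F1")
    f2 = res.validate(X.iloc[:5], y[:5], variant="F2")
    assert f1.q2_ext != f2.q2_ext
    rep = res.validate(X.iloc[:3], np.full(3, y.mean()))
    assert not rep.r2_ext_defined


def test_y_randomize_identity_control_and_reproducibility():
    X, y, _ = gen_linear(LinearGenSpec(n=40, k=3, beta=(2.0, 1.0, -1.0),
                                       sigma=1.0, seed=4))
    res = fit_mlr(X, y)
    ident = res.y_randomize(permutations=[np.arange(len(y))])
    assert ident.mean_r2 == pytest.approx(res.rsquared, abs=1e-12)
    a = res.y_randomize(n_perm=20, seed=99)
    b = res.y_randomize(n_perm=20, seed=99)
    assert a.r2_values == b.r2_values
    assert a.mean_r2 < res.rsquared


def test_y_randomize_null_mean_matches_expectation():
    # permuting breaks X-y association: E[R2] ~ k/(n-1)
    X, y, _ = gen_linear(LinearGenSpec(n=54, k=4, beta=(3.0, -2.0, 1.0, 0.5),
                                       sigma=1.0, seed=8))
    res = fit_mlr(X, y)
    yr = res.y_randomize(n_perm=300, seed=0)
    assert yr.mean_r2 == pytest.approx(4 / 53, abs=0.03)


def test_stepwise_finds_planted_signal(rng):
    n = 100
    X = pd.DataFrame(rng.normal(size=(n, 20)),
                     columns=[f"x{j}" for j in range(20)])
    y = 5.0 * X["x7"].to_numpy() + rng.normal(size=n)
    sel, trace = stepwise_select(X, y)
    assert "x7" in sel
    assert trace.steps[0] == ("enter", "x7", pytest.approx(0.0, abs=1e-6))


def test_stepwise_null_and_single_candidate(rng):
    n = 100
    X = pd.DataFrame(rng.normal(size=(n, 15)),
                     columns=[f"x{j}" for j in range(15)])
    y = rng.normal(size=n)
    sel, trace = stepwise_select(X, y, p_enter=0.05)
    assert len(sel) <= 4  # a few chance entries at most
    x = rng.normal(size=n)
    sel2, _ = stepwise_select(pd.DataFrame({"x": x}), 2 * x + 0.1 * rng.normal(size=n))
    assert sel2 == ["x"]
    with pytest.raises(ValueError):
        stepwise_select(X, y, p_enter=0.0)


def test_confidence_interval_coverage_nominal():
    # 95% CIs should cover the true slope at ~nominal rate
    true = (3.0, -2.0, 1.0, 0.5)
    hits = 0
    n_rep = 400
    for seed in range(n_rep):
        X, y, _ = gen_linear(LinearGenSpec(n=54, k=4, intercept=1.0,
                                           beta=true, sigma=2.0, seed=seed))
        res = fit_mlr(X, y)
        lo, hi = res._sm.conf_int(alpha=0.05).loc["x1"]
        hits += lo <= true[0] <= hi
    assert hits / n_rep == pytest.approx(0.95, abs=0.05)


def test_summary_contains_key_statistics():
    X, y, _ = gen_linear(LinearGenSpec(n=50, k=2, beta=(4.0, 0.0),
                                       sigma=0.5, seed=1))
    s = fit_mlr(X, y).summary()
    assert "R2=" in s and "VIF" in s and "x1" in s and "<0.001" in s
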