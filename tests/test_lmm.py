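"""Weighted random-intercept REML engine: oracles, invariances, inference."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from munmeta.lmm import (
    RankDeficientError, WeightVector, build_weights, fit_weighted_lmm,
    variance_partition, wald_p_values,
)


def _ri_data(seed=0, n_groups=10, per_group=4, sd_u=5.0, sd_e=2.0, weighted=True):
    rng = np.random.default_rng(seed)
    g = np.repeat([f"s{i}" for i in range(n_groups)], per_group)
    n = len(g)
    x1 = rng.normal(10, 3, n)
    x2 = rng.normal(17, 2, n)
    w = build_weights(rng.gamma(16, 0.625, n)) if weighted else WeightVector(np.ones(n))
    u = rng.normal(0, sd_u, n_groups)[np.repeat(np.arange(n_groups), per_group)]
    y = -50 + 8 * x1 + 6 * x2 + u + rng.normal(0, sd_e / np.sqrt(w.values))
    X = pd.DataFrame({"intercept": 1.0, "x1": x1, "x2": x2})
    return y, X, g, w


# -- weights ---------------------------------------------------------------

def test_build_weights_examples():
    np.testing.assert_allclose(build_weights([1, 1, 1]).values, [1, 1, 1])
    np.testing.assert_allclose(build_weights([1, 2]).values, [1.6, 0.4])
    np.testing.assert_allclose(build_weights([None, None]).values, [1, 1])


@given(st.lists(st.floats(min_value=0.1, max_value=50), min_size=1, max_size=40))
def test_weights_always_mean_one(sems):
    assert build_weights(sems).values.mean() == pytest.approx(1.0, abs=1e-12)


def test_mixed_present_absent_sem_is_an_error():
    with pytest.raises(ValueError, match="absent"):
        build_weights([1.0, None, 2.0])
    with pytest.raises(ValueError):
        build_weights([1.0, -2.0])


# -- oracles ---------------------------------------------------------------

@pytest.mark.parametrize("seed", range(5))
def test_collapses_to_weighted_least_squares_without_study_variance(seed):
    """With one record per study the fit equals closed-form WLS normal equations."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 31))
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
    X.insert(0, "intercept", 1.0)
    y = rng.normal(size=n)
    w = build_weights(rng.uniform(0.5, 3.0, n))
    with pytest.warns(UserWarning, match="one record per study"):
        fit = fit_weighted_lmm(y, X, np.arange(n), w)
    W = np.diag(w.values)
    beta = np.linalg.solve(X.T @ W @ X.to_numpy(), X.T @ W @ y)
    got = np.array(list(fit.coefficients.values()))
    assert np.max(np.abs(got - beta) / np.maximum(np.abs(beta), 1e-12)) < 1e-8
    assert fit.var_study == 0.0


def test_matches_statsmodels_mixedlm_on_unweighted_data():
    """Independent REML oracle: statsmodels MixedLM, plain random intercept."""
    sm = pytest.importorskip("statsmodels.api")
    y, X, g, _ = _ri_data(seed=3, weighted=False)
    fit = fit_weighted_lmm(y, X, g)
    m = sm.MixedLM(y, X, groups=g).fit(reml=True)
    np.testing.assert_allclose(list(fit.coefficients.values()), m.params[:3], rtol=1e-5)
    assert fit.var_study == pytest.approx(float(m.cov_re.iloc[0, 0]), rel=1e-4)
    assert fit.var_resid == pytest.approx(float(m.scale), rel=1e-4)
    assert fit.loglik_reml == pytest.approx(m.llf, abs=1e-6)


# -- invariances -----------------------------------------------------------

def test_response_scale_equivariance():
    y, X, g, w = _ri_data(seed=4)
    f1 = fit_weighted_lmm(y, X, g, w)
    c = 3.7
    f2 = fit_weighted_lmm(c * y, X, g, w)
    for t in f1.coefficients:
        assert f2.coefficients[t] == pytest.approx(c * f1.coefficients[t], rel=1e-6)
    assert f2.rsd == pytest.approx(c * f1.rsd, rel=1e-6)
    assert f2.var_study == pytest.approx(c**2 * f1.var_study, rel=1e-5)
    assert f2.var_resid == pytest.approx(c**2 * f1.var_resid, rel=1e-5)


def test_sem_rescaling_leaves_fit_unchanged():
    """Multiplying every SEm by a constant is absorbed by the normalization."""
    rng = np.random.default_rng(6)
    y, X, g, _ = _ri_data(seed=6, weighted=False)
    sem = rng.gamma(16, 0.625, len(y))
    f1 = fit_weighted_lmm(y, X, g, build_weights(sem))
    f2 = fit_weighted_lmm(y, X, g, build_weights(10.0 * sem))
    for t in f1.coefficients:
        assert f2.coefficients[t] == pytest.approx(f1.coefficients[t], rel=1e-9)
    assert f2.var_study == pytest.approx(f1.var_study, rel=1e-7, abs=1e-12)


def test_record_order_invariance():
    y, X, g, w = _ri_data(seed=8)
    perm = np.random.default_rng(1).permutation(len(y))
    f1 = fit_weighted_lmm(y, X, g, w)
    f2 = fit_weighted_lmm(y[perm], X.iloc[perm].reset_index(drop=True), g[perm],
                          WeightVector(w.values[perm]))
    for t in f1.coefficients:
        assert f2.coefficients[t] == pytest.approx(f1.coefficients[t], rel=1e-8)


# -- diagnostics and errors -------------------------------------------------

def test_rank_deficiency_lists_aliased_terms():
    rng = np.random.default_rng(0)
    x = rng.normal(size=20)
    X = pd.DataFrame({"intercept": 1.0, "x": x, "x_twice": 2 * x})
    with pytest.raises(RankDeficientError, match="x_twice|x"):
        fit_weighted_lmm(rng.normal(size=20), X, np.repeat(np.arange(5), 4))


def test_variance_partition():
    y, X, g, w = _ri_data(seed=9, sd_u=5.0)
    fit = fit_weighted_lmm(y, X, g, w)
    s, r = variance_partition(fit)
    assert s + r == pytest.approx(100.0, abs=1e-9)
    fit.var_study, fit.var_resid = 3.0, 1.0
    assert variance_partition(fit) == (75.0, 25.0)
    fit.var_study = 0.0
    assert variance_partition(fit) == (0.0, 100.0)
    fit.var_resid = 0.0
    with pytest.raises(ValueError):
        variance_partition(fit)


def test_wald_p_values_limits():
    y, X, g, w = _ri_data(seed=10)
    fit = fit_weighted_lmm(y, X, g, w)
    assert wald_p_values(fit) == pytest.approx(fit.p_values)
    fit.coefficients["x1"] = 0.0
    assert wald_p_values(fit)["x1"] == pytest.approx(1.0)
    fit.coefficients["x1"] = 1e12
    assert wald_p_values(fit)["x1"] < 1e-12
    fit.coef_se["x1"] = 0.0
    with pytest.raises(ValueError, match="zero standard error"):
        wald_p_values(fit)


def test_null_covariate_type_one_error_is_nominal():
    """A covariate unrelated to the response is rejected at ~alpha=0.05."""
    rng = np.random.default_rng(12345)
    n_groups, per_group, reps = 12, 3, 500
    rejections = 0
    for _ in range(reps):
        g = np.repeat(np.arange(n_groups), per_group)
        n = len(g)
        z = rng.normal(size=n)  # null covariate
        u = rng.normal(0, 2, n_groups)[g]
        w = build_weights(rng.gamma(16, 0.625, n))
        y = 5 + u + rng.normal(0, 1.5 / np.sqrt(w.values))
        X = pd.DataFrame({"intercept": 1.0, "z": z})
        fit = fit_weighted_lmm(y, X, g, w)
        rejections += fit.p_values["z"] < 0.05
    rate = rejections / reps
    assert 0.03 < rate < 0.075, f"type-I error rate {rate}"


def test_reml_objective_profile_is_well_behaved():
    """The selected variance ratio beats nearby ratios and the boundary."""
    from munmeta.lmm import _Profile
    y, X, g, w = _ri_data(seed=2, sd_u=6.0)
    fit = fit_weighted_lmm(y, X, g, w)
    lam_hat = fit.var_study / fit.var_resid
    codes, _ = pd.factorize(g)
    order = np.argsort(codes, kind="stable")
    bounds = np.flatnonzero(np.diff(codes[order])) + 1
    slices = [slice(a, b) for a, b in zip(np.r_[0, bounds], np.r_[bounds, len(y)])]
    prof = _Profile(y[order], X.to_numpy(float)[order], w.values[order], slices)
    f_hat = prof.objective(lam_hat)
    for lam in (0.0, 0.5 * lam_hat, 2.0 * lam_hat, 10.0):
        assert prof.objective(lam) >= f_hat - 1e-7
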