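"""Strategy families: backward-AIC, fractional polynomials, MFP, penalized."""

import numpy as np
import pandas as pd
import pytest

from batchsurv.cox import CoxPH
from batchsurv.errors import ValidationError
from batchsurv.strategies import (
    LAMBDA_GRID,
    ModelStrategy,
    backward_aic,
    build_strategy_model,
    fp_transform,
    mfp_select,
    refit_selected,
)


def simulate_surv(rng, n, beta, censor_scale=2.0):
    p = len(beta)
    Z = rng.standard_normal((n, p))
    t = rng.exponential(np.exp(-(Z @ np.asarray(beta))))
    c = rng.exponential(censor_scale, n)
    T, E = np.minimum(t, c), (t <= c).astype(int)
    cols = [f"x{i}" for i in range(p)]
    return T, E, pd.DataFrame(Z, columns=cols)


# -- backward AIC -----------------------------------------------------------


def test_backward_aic_drops_noise_covariate():
    rng = np.random.default_rng(0)
    dropped = 0
    for _ in range(50):
        T, E, Z = simulate_surv(rng, 300, [1.0, 0.0])
        res = backward_aic(T, E, Z)
        if "x1" not in res.selected:
            dropped += 1
    # AIC keeps a pure-noise covariate with probability P(chi2_1 > 2) ~ 0.157,
    # so the drop rate concentrates near 0.84
    assert dropped >= 38  # >= 75% of replicates


def test_backward_aic_never_beats_full_model_aic():
    rng = np.random.default_rng(1)
    for _ in range(10):
        T, E, Z = simulate_surv(rng, 80, [0.0, 0.0, 0.0])
        res = backward_aic(T, E, Z)
        full = CoxPH(T, E, Z).fit()
        assert res.aic <= full.aic + 1e-9


def test_backward_aic_single_candidate_matches_null_comparison():
    rng = np.random.default_rng(2)
    T, E, Z = simulate_surv(rng, 100, [0.05])
    res = backward_aic(T, E, Z)
    uni = CoxPH(T, E, Z).fit()
    null = CoxPH(T, E, None).fit()
    expect_kept = uni.aic < null.aic
    assert (len(res.selected) == 1) == expect_kept


# -- fractional polynomials -------------------------------------------------


@pytest.mark.parametrize(
    "x,powers,expected",
    [
        (np.array([2.0, 3.0]), (1,), [[2.0], [3.0]]),
        (np.array([np.e]), (0,), [[1.0]]),
        (np.array([2.0]), (2, 2), [[4.0, 4.0 * np.log(2.0)]]),
        (np.array([4.0]), (0.5,), [[2.0]]),
    ],
)
def test_fp_transform_values(x, powers, expected):
    assert np.allclose(fp_transform(x, powers), expected)


def test_fp_transform_rejects_nonpositive():
    with pytest.raises(ValidationError):
        fp_transform(np.array([-1.0, 2.0]), (1,))


def test_mfp_prefers_linear_when_truth_is_linear():
    rng = np.random.default_rng(3)
    linear = 0
    n_rep = 25
    for _ in range(n_rep):
        n = 150
        x = rng.standard_normal(n)
        t = rng.exponential(np.exp(-0.8 * x))
        c = rng.exponential(2.0, n)
        T, E = np.minimum(t, c), (t <= c).astype(int)
        res = mfp_select(T, E, pd.DataFrame({"x": x}), fp_alpha=0.05, select=0.05)
        if res.forms["x"] == (1.0,):
            linear += 1
    assert linear >= 0.8 * n_rep


def test_mfp_log_effect_scores_power_zero_highly():
    from batchsurv.strategies import _fp1_combos, _mfp_design, _fit_ll, fp_shift, fp_scale

    rng = np.random.default_rng(4)
    hits = 0
    n_rep = 20
    for _ in range(n_rep):
        n = 200
        x = rng.uniform(0.2, 5.0, n)
        t = rng.exponential(np.exp(-1.2 * np.log(x)))
        c = rng.exponential(2.0, n)
        T, E = np.minimum(t, c), (t <= c).astype(int)
        shift = fp_shift(x)
        scale = fp_scale(x, shift)
        lls = {}
        for p in _fp1_combos():
            X = _mfp_design(pd.DataFrame({"x": x}), {"x": p}, {"x": shift}, {"x": scale})
            lls[p] = _fit_ll(T, E, X)
        top2 = sorted(lls, key=lls.get, reverse=True)[:2]
        if (0.0,) in top2:
            hits += 1
    assert hits > 0.5 * n_rep


def test_mfp_noise_exclusion_tracks_select_level():
    rng = np.random.default_rng(5)
    excluded = 0
    n_rep = 40
    select = 0.15
    for _ in range(n_rep):
        n = 150
        x = rng.standard_normal(n)
        t = rng.exponential(1.0, n)
        c = rng.exponential(2.0, n)
        T, E = np.minimum(t, c), (t <= c).astype(int)
        res = mfp_select(T, E, pd.DataFrame({"x": x}), select=select)
        if res.forms["x"] is None:
            excluded += 1
    # exclusion frequency ~ 1 - select (closed test is approximately sized)
    assert abs(excluded / n_rep - (1 - select)) < 0.15


# -- penalized fits ---------------------------------------------------------


def test_lasso_all_zero_when_kkt_holds_at_null():
    rng = np.random.default_rng(6)
    T, E, Z = simulate_surv(rng, 120, [0.5, -0.3, 0.2])
    model = CoxPH(T, E, (Z - Z.mean()) / Z.std(ddof=0))
    _, grad0, _ = model.score_info(np.zeros(3))
    lam = float(np.max(np.abs(grad0))) * 1.01  # KKT: |score_j(0)| <= lam for all j
    res = CoxPH(T, E, Z).fit_regularized("l1", lam=lam)
    assert (res.params == 0).all()


def test_lasso_small_lambda_matches_unpenalized():
    rng = np.random.default_rng(7)
    T, E, Z = simulate_surv(rng, 150, [0.6, -0.4, 0.0])
    free = CoxPH(T, E, Z).fit()
    pen = CoxPH(T, E, Z).fit_regularized("l1", lam=1e-6)
    assert np.allclose(pen.params, free.params, atol=1e-3)


def test_lasso_sparsity_monotone_in_lambda():
    rng = np.random.default_rng(8)
    for _ in range(20):
        T, E, Z = simulate_surv(rng, 100, [0.8, -0.5, 0.3, 0.0, 0.0])
        sizes = [
            len(CoxPH(T, E, Z).fit_regularized("l1", lam=lam).selected)
            for lam in LAMBDA_GRID
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:])), sizes


def test_adaptive_lasso_shrinks_strong_coefficient_less():
    rng = np.random.default_rng(9)
    wins = 0
    n_rep = 50
    for _ in range(n_rep):
        T, E, Z = simulate_surv(rng, 150, [1.0, 0.2])
        lasso = CoxPH(T, E, Z).fit_regularized("l1", lam=8.0)
        alasso = CoxPH(T, E, Z).fit_regularized("adaptive_l1", lam=8.0)
        if abs(alasso.params["x0"]) >= abs(lasso.params["x0"]) - 1e-12:
            wins += 1
    assert wins >= 0.8 * n_rep


def test_scad_leaves_large_coefficients_nearly_unbiased():
    rng = np.random.default_rng(10)
    T, E, Z = simulate_surv(rng, 400, [1.2, 0.0])
    free = CoxPH(T, E, Z).fit()
    lam = 6.0
    lasso = CoxPH(T, E, Z).fit_regularized("l1", lam=lam)
    scad = CoxPH(T, E, Z).fit_regularized("scad", lam=lam)
    assert abs(scad.params["x0"] - free.params["x0"]) < abs(
        lasso.params["x0"] - free.params["x0"]
    )


def test_refit_removes_shrinkage_componentwise():
    rng = np.random.default_rng(11)
    T, E, Z = simulate_surv(rng, 150, [0.9, -0.6, 0.0])
    lasso = CoxPH(T, E, Z).fit_regularized("l1", lam=6.0)
    assert 0 < len(lasso.selected) < 3
    refit = refit_selected(T, E, Z, lasso.selected)
    for name in lasso.selected:
        assert abs(refit.params[name]) >= abs(lasso.params[name]) - 1e-10
        assert refit.params[name] != lasso.params[name]


def test_refit_empty_selection_gives_null_model():
    rng = np.random.default_rng(12)
    T, E, Z = simulate_surv(rng, 50, [0.1])
    res = refit_selected(T, E, Z, [])
    assert len(res.params) == 0
    assert np.allclose(res.linear_predictor(Z), 0.0)


def test_refit_all_candidates_reduces_to_full_fit():
    rng = np.random.default_rng(13)
    T, E, Z = simulate_surv(rng, 100, [0.5, -0.5])
    full = CoxPH(T, E, Z).fit()
    refit = refit_selected(T, E, Z, list(Z.columns))
    assert np.allclose(full.params, refit.params, atol=1e-10)


# -- dispatch ---------------------------------------------------------------


def test_strategy_dispatch_families():
    rng = np.random.default_rng(14)
    T, E, Z = simulate_surv(rng, 120, [0.8, 0.0, -0.5])
    for strat in (
        ModelStrategy(name="Null", candidates=()),
        ModelStrategy(name="Uni", selection="univariate", candidates=("x0",)),
        ModelStrategy(name="bwAIC", selection="backward_aic"),
        ModelStrategy(name="Lasso-3", selection="l1", penalty_lambda=1.0),
        ModelStrategy(name="Lasso_Cox-3", selection="l1", penalty_lambda=1.0, refit_unpenalized=True),
    ):
        sfit = build_strategy_model(strat, T, E, Z)
        lp = sfit.linear_predictor(Z)
        assert lp.shape == (120,)
        if strat.name == "Null":
            assert np.allclose(lp, 0.0)
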