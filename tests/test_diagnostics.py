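"""Selection stability and omitted-covariate diagnostics."""

import numpy as np
import pandas as pd
import pytest

from batchsurv import make_folds_stratified, run_cv
from batchsurv.cohort import SurvivalCohort
from batchsurv.cox import CoxPH
from batchsurv.diagnostics import (
    kuncheva_index,
    omitted_martingale,
    omitted_sens_spec_models,
    selection_frequency,
    stability_report,
)
from batchsurv.errors import ConfigurationError, ValidationError
from batchsurv.resampling import CVResult, FoldPlan
from batchsurv.strategies import ModelStrategy

from conftest import make_cohort_df


# -- Kuncheva ---------------------------------------------------------------


@pytest.mark.parametrize(
    "a,b,N,expected",
    [
        ({"x", "y", "z"}, {"x", "y", "z"}, 9, 1.0),
        ({"a", "b", "c"}, {"c", "d", "e"}, 9, 0.0),  # r = 1 = s^2/N exactly
        ({"a", "b", "c"}, {"c", "d", "e"}, 10, (1 - 0.9) / (3 - 0.9)),
    ],
)
def test_kuncheva_worked_values(a, b, N, expected):
    assert kuncheva_index(a, b, N) == pytest.approx(expected)
    assert kuncheva_index(b, a, N) == pytest.approx(expected)  # symmetry


def test_kuncheva_one_iff_equal():
    assert kuncheva_index({"a", "b"}, {"a", "b"}, 5) == 1.0
    assert kuncheva_index({"a", "b"}, {"a", "c"}, 5) < 1.0


def test_kuncheva_undefined_cases():
    with pytest.raises(ValidationError):
        kuncheva_index({"a", "b"}, {"a", "b"}, 2)  # s = N
    with pytest.raises(ValidationError):
        kuncheva_index({"a"}, {"a", "b"}, 5)  # unequal sizes


# -- selection frequency ----------------------------------------------------


def _cv_with_selections(selections, candidates):
    models = pd.DataFrame(
        {
            "rep": range(len(selections)),
            "fold": [0] * len(selections),
            "selected": [list(s) for s in selections],
            "coefficients": [{} for _ in selections],
        }
    )
    plan = FoldPlan("A", 1, len(selections), 0, pd.DataFrame())
    return CVResult(
        plan=plan,
        strategy=ModelStrategy(name="S", candidates=tuple(candidates)),
        time_grid=[7.0],
        models=models,
    )


def test_selection_frequency_forced_and_absent():
    cv = _cv_with_selections([{"G1"}, {"G1"}, {"G1", "G2"}], ["G1", "G2", "G3"])
    freq = selection_frequency(cv)
    assert freq["G1"] == 1.0
    assert freq["G2"] == pytest.approx(1 / 3)
    assert freq["G3"] == 0.0


def test_stability_report_fixed_size_sets():
    cv = _cv_with_selections([{"a", "b"}, {"a", "b"}, {"a", "c"}], list("abcde"))
    rep = stability_report(cv)
    assert -1 <= rep.mean_kuncheva <= 1
    assert rep.pairwise["kuncheva"].iloc[0] == 1.0  # first two sets identical


def test_lasso_max_lambda_on_noise_selects_nothing():
    rng = np.random.default_rng(0)
    low_freq = []
    for seed in range(5):
        n = 80
        Z = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("abcd"))
        T = rng.exponential(1.0, n)
        E = np.ones(n, dtype=int)
        res = CoxPH(T, E, Z).fit_regularized("l1", lam=100.0)
        low_freq.append(len(res.selected))
    assert np.mean(low_freq) < 0.5


# -- Martingale residuals ---------------------------------------------------


def _signal_cohort(n, seed, beta_omitted=0.0):
    rng = np.random.default_rng(seed)
    g1 = rng.standard_normal(n)
    c0 = rng.standard_normal(n)  # the candidate-excluded covariate
    lam = 0.08 * np.exp(0.8 * g1 + beta_omitted * c0)
    t = rng.exponential(1 / lam)
    T = np.minimum(t, 14.0)
    E = (t <= 14.0).astype(int)
    df = make_cohort_df(
        T, E, [f"B{i % 6 + 1}" for i in range(n)], ["train"] * n, G1=g1, C0=c0
    )
    return SurvivalCohort(df, {"G1": "gene", "C0": "clinical_continuous"})


def _cv_univariate(cohort, seed, n_rep=2):
    plan = make_folds_stratified(cohort, 3, n_rep, seed=seed)
    strat = ModelStrategy(name="Uni", selection="univariate", candidates=("G1",))
    return run_cv(cohort, plan, strat, [7.0])


def test_martingale_residuals_sum_to_zero_within_fit():
    cohort = _signal_cohort(90, seed=1)
    cv = _cv_univariate(cohort, seed=2)
    sums = cv.residuals.groupby(["rep", "fold"])["martingale"].sum()
    assert np.allclose(sums, 0.0, atol=1e-8)


def test_omitted_martingale_null_covariate_uncorrelated():
    cohort = _signal_cohort(500, seed=3, beta_omitted=0.0)
    cv = _cv_univariate(cohort, seed=4)
    rep = omitted_martingale(cohort, cv, "C0")
    assert abs(rep.spearman_rho) < 0.1
    assert set(rep.smooth.columns) == {"x", "fitted"}


def test_omitted_martingale_detects_strong_effect():
    hits = 0
    n_rep = 20
    for seed in range(n_rep):
        cohort = _signal_cohort(200, seed=seed + 10, beta_omitted=0.9)
        cv = _cv_univariate(cohort, seed=seed, n_rep=1)
        rep = omitted_martingale(cohort, cv, "C0")
        if rep.spearman_p < 0.05:
            hits += 1
    assert hits >= 0.8 * n_rep


def test_omitted_covariate_must_not_be_candidate():
    cohort = _signal_cohort(60, seed=5)
    cv = _cv_univariate(cohort, seed=6)
    with pytest.raises(ConfigurationError):
        omitted_martingale(cohort, cv, "G1")


# -- logistic sens/spec models ----------------------------------------------


def _fake_cv_scores(scores: pd.DataFrame, candidates=("G1",)):
    plan = FoldPlan("A", 1, 1, 0, pd.DataFrame())
    return CVResult(
        plan=plan,
        strategy=ModelStrategy(name="S", candidates=tuple(candidates)),
        time_grid=[7.0],
        scores=scores,
    )


def test_logistic_or_matches_contingency_table():
    """Binary omitted covariate, dead-by-t patients: 8/10 with M > c when
    Z = 1 vs 4/10 when Z = 0 -> OR = (8*6)/(2*4) = 6."""
    n_dead = 20
    z = np.array([1] * 10 + [0] * 10)
    above = np.array([1] * 8 + [0] * 2 + [1] * 4 + [0] * 6)
    lp = np.where(above == 1, 1.0, -1.0)  # cutoff 0 splits exactly at 'above'
    dead = pd.DataFrame(
        {
            "rep": 0,
            "fold": 0,
            "patient_id": [f"D{i}" for i in range(n_dead)],
            "time": 3.0,
            "event": 1,
            "lp": lp,
        }
    )
    alive = pd.DataFrame(
        {
            "rep": 0,
            "fold": 0,
            "patient_id": [f"A{i}" for i in range(10)],
            "time": 12.0,
            "event": 0,
            "lp": np.linspace(-1, 1, 10),
        }
    )
    scores = pd.concat([dead, alive], ignore_index=True)
    cohort_df = make_cohort_df(
        scores["time"], scores["event"], ["B1"] * 30, ["train"] * 30,
        G1=np.zeros(30) + np.arange(30) * 0.01,  # non-constant candidate
        Z=np.concatenate([z, np.tile([0, 1], 5)]).astype(float),
    )
    cohort_df["patient_id"] = scores["patient_id"]
    cohort = SurvivalCohort(cohort_df, {"G1": "gene", "Z": "clinical_binary"})
    cv = _fake_cv_scores(scores)
    rep = omitted_sens_spec_models(cohort, cv, "Z", t=7.0, cutoffs=[0.0])
    row = rep.logistic[(rep.logistic["side"] == "sensitivity")].iloc[0]
    assert row["or_"] == pytest.approx(6.0, rel=1e-4)
    assert row["sens"] == pytest.approx(12 / 20)


def test_degenerate_cutoff_reported_missing():
    cohort = _signal_cohort(80, seed=7)
    cv = _cv_univariate(cohort, seed=8, n_rep=1)
    low = float(cv.scores["lp"].min()) - 10.0  # below all markers
    rep = omitted_sens_spec_models(cohort, cv, "C0", t=7.0, cutoffs=[low])
    sens_rows = rep.logistic[rep.logistic["side"] == "sensitivity"]
    assert sens_rows["or_"].isna().all()
    assert (sens_rows["reason"] == "single-class response").all()
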