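"""Sample-size planning, final fitting, and independent test-set validation.

The number of death events needed to size the test set follows Schoenfeld's
clinical-trial formula adapted to a two-group prognostic index: to test
``H0: hazard ratio = 1`` against ``H1: hazard ratio = Delta0`` at one-sided
level alpha with a given power, the required event count is

    (z_power + z_{1-alpha})^2 / (p_A p_B (ln Delta0)^2)

with p_A, p_B the two group proportions. The final model is fitted once on
the full training set; its frozen coefficients and baseline hazard are then
evaluated on the independent test set, with percentile bootstrap confidence
intervals from patient-level resampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SurvivalCohort
from .errors import ConfigurationError, ValidationError
from .metrics import brier_score, c_index, td_auc, _surv_col
from .strategies import ModelStrategy, StrategyFit, build_strategy_model

__all__ = [
    "SampleSizeInputs",
    "schoenfeld_events",
    "final_fit",
    "validate_on_test",
    "bootstrap_ci",
    "ValidationReport",
]


@dataclass(frozen=True)
class SampleSizeInputs:
    """Inputs for the Schoenfeld event-count formula.

    ``alpha`` is one-sided; pass alpha/2 for a two-sided design. ``power``
    is the target power (e.g. 0.80). ``hr_alt`` is the hazard ratio under
    the alternative; ``p_a``/``p_b`` the prognostic-group proportions.
    """

    alpha: float = 0.05
    power: float = 0.80
    hr_alt: float = 2.0
    p_a: float = 0.5
    p_b: float = 0.5

    def __post_init__(self):
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ConfigurationError("alpha and power must be in (0,1)")
        if self.hr_alt <= 0:
            raise ConfigurationError("hr_alt must be positive")
        if self.hr_alt == 1.0:
            raise ConfigurationError("hr_alt = 1: ln(Delta0) = 0, formula undefined")
        if abs(self.p_a + self.p_b - 1.0) > 1e-9:
            raise ConfigurationError("p_a + p_b must equal 1")


def schoenfeld_events(inputs: SampleSizeInputs) -> int:
    """Required number of events (ceiling of the Schoenfeld formula)."""
    z_power = stats.norm.ppf(inputs.power)
    z_alpha = stats.norm.ppf(1.0 - inputs.alpha)
    value = (z_power + z_alpha) ** 2 / (
        inputs.p_a * inputs.p_b * math.log(inputs.hr_alt) ** 2
    )
    return int(math.ceil(value))


def final_fit(train: SurvivalCohort, strategy: ModelStrategy) -> StrategyFit:
    """Build the candidate model on the entire training dataset.

    The selected set on the full data may differ from the modal selection
    across cross-validation folds; this is reported as-is, never forced to
    agree.
    """
    df = train.train().df if (train.df["role"] == "test").any() else train.df
    cand = (
        list(strategy.candidates)
        if strategy.candidates is not None
        else train.covariate_names
    )
    return build_strategy_model(
        strategy, df["time"].to_numpy(), df["event"].to_numpy(), df[cand]
    )


def hazard_ratio_table(sfit: StrategyFit) -> pd.DataFrame:
    """HR = exp(beta) with Wald p per selected covariate (empty for the
    null model)."""
    summ = sfit.results.summary()
    return summ.loc[summ["coef"] != 0, ["coef", "HR", "se", "p"]]


@dataclass
class ValidationReport:
    """Test-set point estimates and bootstrap confidence intervals."""

    hr_table: pd.DataFrame = field(repr=False, default=None)
    curves: pd.DataFrame = field(repr=False, default=None)  # indicator, time, value
    ci: pd.DataFrame = field(repr=False, default=None)  # indicator, time, lo, hi
    n_test: int = 0


def _test_frame(sfit: StrategyFit, test: SurvivalCohort, time_grid) -> pd.DataFrame:
    df = test.test().df if (test.df["role"] == "train").any() else test.df
    cand_cols = df.columns
    needed = sfit.selected
    missing = [c for c in needed if c not in cand_cols]
    if missing:
        raise ValidationError(f"covariate(s) missing in test data: {missing}")
    cand = (
        list(sfit.strategy.candidates)
        if sfit.strategy.candidates is not None
        else [c for c in df.columns if c not in ("patient_id", "time", "event", "batch", "role")]
    )
    lp = sfit.linear_predictor(df[cand])
    surv = sfit.predict_survival(df[cand], time_grid)
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"].to_numpy(),
            "time": df["time"].to_numpy(dtype=float),
            "event": df["event"].to_numpy(dtype=int),
            "lp": lp,
        }
    )
    for j, t in enumerate(np.atleast_1d(time_grid)):
        out[_surv_col(float(t))] = surv[:, j]
    return out


def _indicators_on(frame: pd.DataFrame, indicators, time_grid) -> pd.DataFrame:
    rows = []
    T = frame["time"].to_numpy()
    E = frame["event"].to_numpy()
    for ind in indicators:
        if ind == "c_index":
            try:
                rows.append({"indicator": ind, "time": np.nan, "value": c_index(frame["lp"], T, E)})
            except ValidationError:
                rows.append({"indicator": ind, "time": np.nan, "value": np.nan})
            continue
        for t in np.atleast_1d(time_grid):
            t = float(t)
            try:
                if ind == "td_auc":
                    val = td_auc(frame["lp"].to_numpy(), T, E, t)
                elif ind == "brier":
                    val = brier_score(frame[_surv_col(t)].to_numpy(), T, E, t)
                else:
                    raise ValidationError(f"unknown indicator {ind!r}")
            except ValidationError:
                val = np.nan
            rows.append({"indicator": ind, "time": t, "value": val})
    return pd.DataFrame(rows)


def validate_on_test(
    sfit: StrategyFit,
    test: SurvivalCohort,
    indicators=("td_auc", "c_index", "brier"),
    time_grid=(7.0,),
) -> ValidationReport:
    """Evaluate a frozen fitted model on the independent test dataset.

    Predictions come from the stored coefficients and training baseline
    hazard only; test-set outcomes enter the indicator computation, never
    the predictions. Deterministic: repeated evaluation is identical.
    """
    frame = _test_frame(sfit, test, time_grid)
    curves = _indicators_on(frame, indicators, time_grid)
    return ValidationReport(
        hr_table=hazard_ratio_table(sfit), curves=curves, n_test=len(frame)
    )


def bootstrap_ci(
    sfit: StrategyFit,
    test: SurvivalCohort,
    indicator: str = "td_auc",
    time_grid=(7.0,),
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Percentile bootstrap CIs for test-set indicators.

    Test patients are resampled with replacement; the model is never refit.
    Resamples where the indicator is undefined (no usable pairs/events at t)
    are skipped and counted; a column flags instability when more than 20%
    were skipped.
    """
    if B < 100:
        raise ConfigurationError("B must be >= 100 for reported CIs")
    frame = _test_frame(sfit, test, time_grid)
    rng = np.random.default_rng(seed)
    n = len(frame)
    eval_times = [np.nan] if indicator == "c_index" else [float(t) for t in np.atleast_1d(time_grid)]
    draws = {t: [] for t in eval_times}
    skipped = {t: 0 for t in eval_times}
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        bs = frame.iloc[idx]
        T = bs["time"].to_numpy()
        E = bs["event"].to_numpy()
        for t in eval_times:
            try:
                if indicator == "c_index":
                    val = c_index(bs["lp"].to_numpy(), T, E)
                elif indicator == "td_auc":
                    val = td_auc(bs["lp"].to_numpy(), T, E, t)
                elif indicator == "brier":
                    val = brier_score(bs[_surv_col(t)].to_numpy(), T, E, t)
                else:
                    raise ConfigurationError(f"unknown indicator {indicator!r}")
                if np.isnan(val):
                    raise ValidationError("undefined")
                draws[t].append(val)
            except ValidationError:
                skipped[t] += 1
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for t in eval_times:
        vals = np.asarray(draws[t])
        unstable = skipped[t] > 0.2 * B
        if len(vals) == 0:
            rows.append({"time": t, "lo": np.nan, "hi": np.nan, "n_skipped": skipped[t], "unstable": True})
            continue
        rows.append(
            {
                "time": t,
                "lo": float(np.quantile(vals, lo_q)),
                "hi": float(np.quantile(vals, hi_q)),
                "n_skipped": skipped[t],
                "unstable": unstable,
            }
        )
    out = pd.DataFrame(rows)
    out.insert(0, "indicator", indicator)
    return out
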