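"""Model-building strategy families.

A strategy is the full recipe re-run inside every training fold: a variable
selection method, a functional form for continuous covariates, the Cox fit,
and an optional penalty. The families mirror the standard low/high
dimensional toolbox: per-covariate univariate models, backward elimination
by AIC (optionally on fractional-polynomial transformed covariates),
multivariable fractional polynomials (MFP), and L1 / adaptive-lasso / SCAD
penalized Cox models, each usable either as a shrunken model or as a pure
selection step followed by an unpenalized refit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy import stats

from .cox import CoxPH, CoxPHResults
from .errors import ConfigurationError, ConvergenceError, ValidationError

logger = logging.getLogger(__name__)

SELECTIONS = ("none", "univariate", "backward_aic", "mfp", "l1", "adaptive_l1", "scad")

#: conventional fractional-polynomial power set
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

#: the lambda grid of the penalized families; suffix k maps to grid[k-1]
LAMBDA_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class ModelStrategy:
    """One model-building recipe (one 'row' of the strategy table).

    Fields irrelevant to the chosen ``selection`` are ignored. For the
    penalized families, larger ``penalty_lambda`` means a sparser model;
    ``refit_unpenalized=True`` turns the penalty into a pure selection step
    followed by an ordinary Cox refit on the selected covariates.
    """

    name: str
    selection: str = "none"
    #: None means "all covariate columns offered"; () the null model
    candidates: tuple[str, ...] | None = None
    functional: str = "linear"  # linear | fractional_polynomial
    fp_alpha: float = 0.05
    mfp_select: float = 0.05
    penalty_lambda: float = 1.0
    refit_unpenalized: bool = False

    def __post_init__(self):
        if self.selection not in SELECTIONS:
            raise ConfigurationError(f"unknown selection method {self.selection!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelStrategy":
        d = dict(d)
        if d.get("candidates") is not None:
            d["candidates"] = tuple(d["candidates"])
        return cls(**d)


# ---------------------------------------------------------------------------
# elementary builders


def backward_aic(time, event, Z: pd.DataFrame, candidates=None) -> CoxPHResults:
    """Backward elimination minimizing AIC = -2 logPL + 2p.

    Starting from the full candidate set, repeatedly drop the single
    covariate whose removal most decreases the AIC; stop when no drop
    improves it. Can end in the null model.
    """
    cand = list(candidates) if candidates is not None else list(Z.columns)
    current = list(cand)
    best = CoxPH(time, event, Z[current] if current else None).fit()
    best_aic = best.aic
    while current:
        trial_results = []
        for name in current:
            reduced = [c for c in current if c != name]
            try:
                res = CoxPH(time, event, Z[reduced] if reduced else None).fit()
            except ConvergenceError:
                continue
            trial_results.append((res.aic, name, res))
        if not trial_results:
            break
        trial_results.sort(key=lambda t: t[0])
        aic, name, res = trial_results[0]
        if aic < best_aic:
            best, best_aic = res, aic
            current.remove(name)
        else:
            break
    return best


def fp_transform(x, powers, shift: float | None = None) -> np.ndarray:
    """Fractional-polynomial basis for one covariate.

    ``x`` must be strictly positive after the (recorded) shift. Power
    ``p != 0`` maps to ``x**p``; ``p == 0`` to ``ln x``; a repeated power
    ``(p, p)`` to ``(x**p, x**p * ln x)``.
    """
    x = np.asarray(x, dtype=float)
    if shift is None:
        shift = 0.0
    xs = x + shift
    if (xs <= 0).any():
        raise ValidationError("nonpositive values after shift in fp_transform")
    powers = tuple(np.atleast_1d(powers))
    cols = []
    prev = None
    for i, p in enumerate(powers):
        base = np.log(xs) if p == 0 else xs ** p
        if i > 0 and p == powers[i - 1]:
            cols.append(prev * np.log(xs))
        else:
            cols.append(base)
        prev = base
    return np.column_stack(cols)


def fp_shift(x) -> float:
    """Origin shift making a covariate strictly positive (0 if already so).

    The minimum is mapped to a tenth of the observed range so that negative
    powers and logs stay well conditioned.
    """
    x = np.asarray(x, dtype=float)
    lo = x.min()
    if lo > 0:
        return 0.0
    span = np.ptp(x)
    return float(-lo + (span / 10.0 if span > 0 else 1.0))


def fp_scale(x, shift: float) -> float:
    """Positive rescaling divisor (median of the shifted values); keeps the
    transformed covariate O(1) across the power grid."""
    x = np.asarray(x, dtype=float) + shift
    med = float(np.median(x))
    return med if med > 0 else 1.0


def _fp1_combos():
    return [(p,) for p in FP_POWERS]


def _fp2_combos():
    return list(combinations_with_replacement(FP_POWERS, 2))


@dataclass
class MFPResult:
    """Outcome of the MFP closed-test procedure."""

    fit: CoxPHResults
    forms: dict[str, tuple[float, ...] | None] = field(default_factory=dict)
    shifts: dict[str, float] = field(default_factory=dict)
    scales: dict[str, float] = field(default_factory=dict)


def _mfp_design(Z: pd.DataFrame, forms: dict, shifts: dict, scales: dict) -> pd.DataFrame:
    """Expand covariates into their current FP bases (shift and scale are
    frozen from the training data so new data map consistently)."""
    blocks = {}
    for name, powers in forms.items():
        if powers is None:
            continue
        if powers == (1.0,):
            blocks[name] = Z[name].to_numpy(dtype=float)[:, None]
        else:
            u = (Z[name].to_numpy(dtype=float) + shifts[name]) / scales[name]
            blocks[name] = fp_transform(u, powers)
    cols, data = [], []
    for name, mat in blocks.items():
        for i in range(mat.shape[1]):
            cols.append(name if mat.shape[1] == 1 else f"{name}__fp{i + 1}")
            data.append(mat[:, i])
    if not data:
        return pd.DataFrame(index=Z.index)
    return pd.DataFrame(np.column_stack(data), columns=cols, index=Z.index)


def _fit_ll(time, event, X: pd.DataFrame) -> float:
    model = CoxPH(time, event, X if X.shape[1] else None)
    return model.fit().llf


def mfp_select(
    time,
    event,
    Z: pd.DataFrame,
    candidates=None,
    fp_alpha: float = 0.05,
    select: float = 0.05,
    binary: set[str] | None = None,
    max_cycles: int = 5,
) -> MFPResult:
    """Multivariable fractional polynomials: joint variable selection and
    power-transform choice by a per-covariate closed test.

    For each continuous covariate in turn (others held at their current
    forms): (1) best-FP2 vs exclusion at level ``select`` on chi2 with 4 df —
    fail to reject drops the covariate; (2) best-FP2 vs linear at level
    ``fp_alpha`` (3 df) — fail to reject keeps it linear; (3) best-FP2 vs
    best-FP1 at ``fp_alpha`` (2 df) decides FP1 vs FP2. Binary covariates
    only face the inclusion test (1 df). Cycling stops when forms stabilize
    or after ``max_cycles``.
    """
    cand = list(candidates) if candidates is not None else list(Z.columns)
    binary = binary or {
        c for c in cand if set(np.unique(Z[c].to_numpy(dtype=float))) <= {0.0, 1.0}
    }
    shifts = {c: fp_shift(Z[c]) for c in cand}
    scales = {c: fp_scale(Z[c], shifts[c]) for c in cand}
    forms: dict[str, tuple[float, ...] | None] = {c: (1.0,) for c in cand}

    def ll_with(name, powers):
        trial = dict(forms)
        trial[name] = powers
        X = _mfp_design(Z, trial, shifts, scales)
        try:
            return _fit_ll(time, event, X)
        except (ConvergenceError, ValidationError, FloatingPointError):
            return -np.inf

    for _cycle in range(max_cycles):
        prev = dict(forms)
        for name in cand:
            ll_null = ll_with(name, None)
            if not np.isfinite(ll_null):
                logger.warning("MFP: null fit failed for %s; form kept this cycle", name)
                continue
            if name in binary:
                ll_lin = ll_with(name, (1.0,))
                if 2 * (ll_lin - ll_null) < stats.chi2.ppf(1 - select, 1):
                    forms[name] = None
                else:
                    forms[name] = (1.0,)
                continue
            # best FP1 and FP2 with others fixed
            ll_fp1, best1 = max(
                ((ll_with(name, p), p) for p in _fp1_combos()), key=lambda t: t[0]
            )
            ll_fp2, best2 = max(
                ((ll_with(name, p), p) for p in _fp2_combos()), key=lambda t: t[0]
            )
            ll_lin = ll_with(name, (1.0,))
            if not np.isfinite(ll_fp2):
                logger.warning("MFP: all FP fits failed for %s; kept linear", name)
                forms[name] = (1.0,) if np.isfinite(ll_lin) else None
                continue
            if 2 * (ll_fp2 - ll_null) < stats.chi2.ppf(1 - select, 4):
                forms[name] = None
            elif np.isfinite(ll_lin) and 2 * (ll_fp2 - ll_lin) < stats.chi2.ppf(1 - fp_alpha, 3):
                forms[name] = (1.0,)
            elif np.isfinite(ll_fp1) and 2 * (ll_fp2 - ll_fp1) < stats.chi2.ppf(1 - fp_alpha, 2):
                forms[name] = best1
            else:
                forms[name] = best2
        if forms == prev:
            break
    X = _mfp_design(Z, forms, shifts, scales)
    fit = CoxPH(time, event, X if X.shape[1] else None).fit()
    return MFPResult(fit=fit, forms=forms, shifts=shifts, scales=scales)


def refit_selected(time, event, Z: pd.DataFrame, selected) -> CoxPHResults:
    """Unpenalized Cox refit on a previously selected covariate set.

    An empty selection yields the null model (linear predictor 0,
    Nelson-Aalen baseline).
    """
    selected = list(selected)
    model = CoxPH(time, event, Z[selected] if selected else None)
    return model.fit()


# ---------------------------------------------------------------------------
# dispatch


@dataclass
class StrategyFit:
    """A strategy executed on one training sample."""

    strategy: ModelStrategy
    results: CoxPHResults
    selected: list[str]
    #: maps candidate name -> FP powers when the MFP family chose transforms
    forms: dict | None = None
    shifts: dict | None = None
    scales: dict | None = None

    def linear_predictor(self, Z: pd.DataFrame) -> np.ndarray:
        X = self._design(Z)
        return self.results.linear_predictor(X)

    def predict_survival(self, Z: pd.DataFrame, times) -> np.ndarray:
        X = self._design(Z)
        return self.results.predict_survival(X, times)

    def _design(self, Z: pd.DataFrame) -> pd.DataFrame:
        if self.forms is not None:
            return _mfp_design(Z, self.forms, self.shifts, self.scales)
        return Z


def build_strategy_model(strategy: ModelStrategy, time, event, Z: pd.DataFrame) -> StrategyFit:
    """Run a full strategy (selection + form + fit + penalty) on one sample."""
    cand = list(strategy.candidates) if strategy.candidates is not None else list(Z.columns)
    missing = [c for c in cand if c not in Z.columns]
    if missing:
        raise ConfigurationError(f"candidate covariate(s) not in data: {missing}")
    Zc = Z[cand]
    sel = strategy.selection
    if sel == "none":
        if not cand:
            res = CoxPH(time, event, None).fit()
        else:
            res = CoxPH(time, event, Zc).fit()
        return StrategyFit(strategy, res, res.selected)
    if sel == "univariate":
        if len(cand) != 1:
            raise ConfigurationError("univariate strategy needs exactly one candidate")
        res = CoxPH(time, event, Zc).fit()
        return StrategyFit(strategy, res, res.selected)
    if sel == "backward_aic":
        res = backward_aic(time, event, Zc)
        return StrategyFit(strategy, res, res.selected)
    if sel == "mfp":
        mfp = mfp_select(
            time, event, Zc, fp_alpha=strategy.fp_alpha, select=strategy.mfp_select
        )
        selected = [c for c, f in mfp.forms.items() if f is not None]
        return StrategyFit(strategy, mfp.fit, selected, mfp.forms, mfp.shifts, mfp.scales)
    # penalized families
    model = CoxPH(time, event, Zc)
    res = model.fit_regularized(penalty=sel, lam=strategy.penalty_lambda)
    selected = res.selected
    if strategy.refit_unpenalized:
        res = refit_selected(time, event, Zc, selected)
    return StrategyFit(strategy, res, selected)


def null_strategy(name: str = "Null") -> ModelStrategy:
    return ModelStrategy(name=name, selection="none", candidates=())
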