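"""Censored-survival performance indicators and their cross-validated
estimation.

Indicators: the Graf inverse-probability-of-censoring-weighted (IPCW) Brier
score BS(t); Harrell's concordance index; the cumulative/dynamic
time-dependent sensitivity, specificity and AUC(t) (cases = dead by t,
controls = alive after t), estimated by Bayes inversion with Kaplan-Meier
survival within marker strata so that censoring is handled without any
smoothing parameter; and a quantile-group calibration check at a fixed time.

Cross-validated aggregation offers the two classical schemes: *pooling*
(concatenate all test-fold scores of a repetition, compute the indicator
once, then average over repetitions) and *averaging* (compute per fold,
average over folds, then repetitions). Pooling predicted-survival scores
under batch-level resampling with outcome-unbalanced batches is biased
downward — the fold-specific baselines make the survival scores
non-comparable — and is therefore computed with an explicit warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "PerformanceEstimate",
    "brier_score",
    "c_index",
    "td_sens_spec",
    "td_auc",
    "aggregate_cv",
    "optimism",
    "calibration_at",
    "reverse_km",
    "km_estimate",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier helpers


def km_estimate(times, events):
    """Kaplan-Meier estimate; returns (unique event times, survival values)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    uniq, d = np.unique(t[e == 1], return_counts=True)
    t_sorted = np.sort(t)
    n_risk = len(t) - np.searchsorted(t_sorted, uniq, side="left")
    surv = np.cumprod(1.0 - d / n_risk)
    return uniq, surv


def _km_at(uniq, surv, t):
    idx = np.searchsorted(uniq, np.atleast_1d(t), side="right")
    out = np.where(idx > 0, np.concatenate([[1.0], surv])[idx], 1.0)
    return out


def reverse_km(times, events):
    """Reverse Kaplan-Meier estimate of the censoring survival Ghat.

    Censorings are the 'events'; deaths are treated as censored. At tied
    times deaths are taken to precede censorings, so the at-risk count for
    a censoring at t excludes the deaths at t.
    Returns a callable ``G(t, left=False)``; ``left=True`` gives the
    left-hand limit Ghat(t-).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    uniq, c = np.unique(t[e == 0], return_counts=True)
    t_sorted = np.sort(t)
    td_sorted = np.sort(t[e == 1])
    at_risk = len(t) - np.searchsorted(t_sorted, uniq, side="left")
    deaths_at = np.searchsorted(td_sorted, uniq, side="right") - np.searchsorted(
        td_sorted, uniq, side="left"
    )
    n_risk = at_risk - deaths_at
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(n_risk > 0, 1.0 - c / np.maximum(n_risk, 1), 0.0)
    surv = np.cumprod(factors)
    grid = np.concatenate([[1.0], surv])

    def G(x, left=False):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        side = "left" if left else "right"
        idx = np.searchsorted(uniq, x, side=side)
        return grid[idx]

    return G


# ---------------------------------------------------------------------------
# indicators


def brier_score(predicted_survival, times, events, t: float) -> float:
    """Graf IPCW estimate of the expected Brier score at time t.

    Patients dying by t contribute ``pi^2 / G(T_i-)``; patients under
    follow-up past t contribute ``(1-pi)^2 / G(t)``; patients censored
    before t contribute 0. ``G`` is the reverse-KM censoring survival on the
    evaluation set. Returns NaN with a warning when ``G(t) = 0``.
    """
    pi = np.asarray(predicted_survival, dtype=float)
    T = np.asarray(times, dtype=float)
    E = np.asarray(events, dtype=int)
    if ((pi < 0) | (pi > 1)).any():
        raise ValidationError("predicted survival outside [0,1]")
    G = reverse_km(T, E)
    g_t = float(G(t)[0])
    if g_t == 0.0:
        warnings.warn(f"censoring survival G({t}) = 0: Brier undefined", stacklevel=2)
        return float("nan")
    dead = (T <= t) & (E == 1)
    alive = T > t
    contrib = np.zeros(len(T))
    g_left = G(T[dead], left=True)
    if (g_left == 0).any():
        warnings.warn("G(T-) = 0 for an event before t: Brier undefined", stacklevel=2)
        return float("nan")
    contrib[dead] = pi[dead] ** 2 / g_left
    contrib[alive] = (1.0 - pi[alive]) ** 2 / g_t
    return float(contrib.sum() / len(T))


def c_index(marker, times, events) -> float:
    """Harrell's concordance index.

    Over pairs where the smaller time is an event time (and the times
    differ), the fraction in which the earlier-dying patient has the larger
    marker; tied markers count 0.5.
    """
    m = np.asarray(marker, dtype=float)
    T = np.asarray(times, dtype=float)
    E = np.asarray(events, dtype=int)
    usable = (T[:, None] < T[None, :]) & (E[:, None] == 1)
    n_usable = usable.sum()
    if n_usable == 0:
        raise ValidationError("no usable pairs for the concordance index")
    conc = usable & (m[:, None] > m[None, :])
    ties = usable & (m[:, None] == m[None, :])
    return float((conc.sum() + 0.5 * ties.sum()) / n_usable)


def td_sens_spec(marker, times, events, c: float, t: float) -> tuple[float, float]:
    """Cumulative/dynamic sensitivity and specificity at threshold c, time t.

    ``sens(c;t) = P(M > c | T <= t)``, ``spec(c;t) = P(M <= c | T > t)``,
    estimated by Bayes inversion with Kaplan-Meier survival within the two
    marker strata: ``sens = (1 - S(t|M>c)) P(M>c) / (1 - S(t))`` and
    ``spec = S(t|M<=c) P(M<=c) / S(t)``, clipped to [0,1]. With no censoring
    before t this reduces exactly to empirical fractions. Undefined sides
    (no deaths by t / all dead by t) are returned as NaN.
    """
    m = np.asarray(marker, dtype=float)
    T = np.asarray(times, dtype=float)
    E = np.asarray(events, dtype=int)
    uniq, surv = km_estimate(T, E)
    s_t = float(_km_at(uniq, surv, t)[0])
    hi = m > c
    p_hi = float(hi.mean())

    def strat_surv(mask):
        if mask.sum() == 0:
            return 1.0
        u, s = km_estimate(T[mask], E[mask])
        return float(_km_at(u, s, t)[0])

    sens = np.nan
    spec = np.nan
    if 1.0 - s_t > 0:
        sens = (1.0 - strat_surv(hi)) * p_hi / (1.0 - s_t)
        sens = float(np.clip(sens, 0.0, 1.0))
    if s_t > 0:
        spec = strat_surv(~hi) * (1.0 - p_hi) / s_t
        spec = float(np.clip(spec, 0.0, 1.0))
    return sens, spec


def td_auc(marker, times, events, t: float) -> float:
    """Area under the cumulative/dynamic ROC at time t.

    Trapezoidal integration of sensitivity against 1-specificity over all
    unique marker thresholds plus the two trivial endpoints. Without
    censoring this equals the Mann-Whitney statistic comparing the dead-by-t
    and alive-after-t marker distributions.
    """
    m = np.asarray(marker, dtype=float)
    # walk the curve in threshold order (c = +inf down to -inf), which is the
    # parametric ROC path; sorting by FPR instead would let floating-point
    # jitter cut staircase corners
    pts = [(0.0, 0.0)]
    for c in np.unique(m)[::-1]:
        sens, spec = td_sens_spec(m, times, events, c, t)
        if np.isnan(sens) or np.isnan(spec):
            raise ValidationError(f"sens/spec undefined at t={t}")
        pts.append((1.0 - spec, sens))
    pts.append((1.0, 1.0))
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    return float(np.trapezoid(tpr, fpr))


# ---------------------------------------------------------------------------
# cross-validation aggregation


@dataclass
class PerformanceEstimate:
    """A cross-validated performance indicator with its dispersion.

    ``values`` holds the point estimate per evaluation time (a single entry
    with ``time = NaN`` for the time-independent C-index); ``per_rep``
    retains the per-repetition values for dispersion assessment.
    """

    indicator: str
    score_type: str
    aggregation: str
    times: np.ndarray
    values: np.ndarray
    per_rep: pd.DataFrame = field(repr=False, default=None)

    def value_at(self, t) -> float:
        if np.isnan(self.times).all():
            return float(self.values[0])
        idx = int(np.argmin(np.abs(self.times - t)))
        return float(self.values[idx])


def _surv_col(t: float) -> str:
    return f"surv_{t:g}"


def _score_for(df: pd.DataFrame, indicator: str, score_type: str, t: float | None):
    """Ranking score (higher = higher risk) for a block of test-fold rows."""
    if score_type == "linear_predictor":
        return df["lp"].to_numpy()
    if score_type == "predicted_survival":
        col = _surv_col(t) if t is not None else [c for c in df if c.startswith("surv_")][-1]
        return -df[col].to_numpy()
    raise ValidationError(f"unknown score_type {score_type!r}")


def _indicator_value(df: pd.DataFrame, indicator: str, score_type: str, t: float | None):
    T = df["time"].to_numpy()
    E = df["event"].to_numpy()
    if indicator == "c_index":
        return c_index(_score_for(df, indicator, score_type, t), T, E)
    if indicator == "td_auc":
        return td_auc(_score_for(df, indicator, score_type, t), T, E, t)
    if indicator == "brier":
        return brier_score(df[_surv_col(t)].to_numpy(), T, E, t)
    raise ValidationError(f"unknown indicator {indicator!r}")


def aggregate_cv(
    cv,
    indicator: str = "td_auc",
    score_type: str = "linear_predictor",
    aggregation: str = "pooled",
    time_grid=None,
) -> PerformanceEstimate:
    """Aggregate test-fold scores of a :class:`~batchsurv.resampling.CVResult`
    into a cross-validated performance estimate.

    ``pooled``: concatenate all test folds of a repetition, compute once per
    repetition, then average over repetitions. ``averaged``: compute per
    fold, average over folds, then over repetitions.
    """
    if aggregation not in ("pooled", "averaged"):
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    if (
        aggregation == "pooled"
        and score_type == "predicted_survival"
        and getattr(cv.plan, "strategy", None) == "B"
    ):
        warnings.warn(
            "pooling predicted-survival scores under batch-level resampling "
            "is biased downward when batches are outcome-unbalanced",
            stacklevel=2,
        )
    if indicator == "c_index":
        eval_times = [None]
    else:
        if time_grid is None:
            time_grid = cv.time_grid
        eval_times = list(np.atleast_1d(time_grid))

    scores = cv.scores
    rows = []
    for t in eval_times:
        for rep, rep_df in scores.groupby("rep"):
            if aggregation == "pooled":
                try:
                    val = _indicator_value(rep_df, indicator, score_type, t)
                except ValidationError:
                    val = np.nan
            else:
                vals = []
                for _, fold_df in rep_df.groupby("fold"):
                    try:
                        vals.append(_indicator_value(fold_df, indicator, score_type, t))
                    except ValidationError:
                        continue
                val = float(np.nanmean(vals)) if vals else np.nan
            rows.append({"time": np.nan if t is None else t, "rep": rep, "value": val})
    per_rep = pd.DataFrame(rows)
    agg = per_rep.groupby("time", dropna=False)["value"].mean()
    times = agg.index.to_numpy(dtype=float)
    return PerformanceEstimate(
        indicator=indicator,
        score_type=score_type,
        aggregation=aggregation,
        times=times,
        values=agg.to_numpy(),
        per_rep=per_rep,
    )


def optimism(cv, indicator: str = "td_auc", time_grid=None) -> pd.DataFrame:
    """Validation surprise: apparent (training-fold) minus test-fold
    indicator, averaged over folds and repetitions, per evaluation time.

    Returns a DataFrame with columns ``time, apparent, validated, optimism``.
    """
    if time_grid is None:
        time_grid = cv.time_grid
    eval_times = [None] if indicator == "c_index" else list(np.atleast_1d(time_grid))
    app = cv.apparent
    rows = []
    for t in eval_times:
        t_key = np.nan if t is None else t
        diffs, apps, vals = [], [], []
        for (rep, fold), fold_df in cv.scores.groupby(["rep", "fold"]):
            sel = app[
                (app["rep"] == rep)
                & (app["fold"] == fold)
                & (app["indicator"] == indicator)
                & (app["time"].isna() if t is None else (app["time"] == t))
            ]
            if sel.empty:
                continue
            a = float(sel["value"].iloc[0])
            try:
                v = _indicator_value(fold_df, indicator, "linear_predictor", t)
            except ValidationError:
                continue
            diffs.append(a - v)
            apps.append(a)
            vals.append(v)
        rows.append(
            {
                "time": t_key,
                "apparent": float(np.mean(apps)) if apps else np.nan,
                "validated": float(np.mean(vals)) if vals else np.nan,
                "optimism": float(np.mean(diffs)) if diffs else np.nan,
            }
        )
    return pd.DataFrame(rows)


def calibration_at(
    predicted_survival, times, events, t: float, n_groups: int = 4
) -> pd.DataFrame:
    """Quantile-group calibration at a fixed time point.

    Patients are grouped by predicted-survival quantiles; per group the mean
    predicted survival is compared with the group's Kaplan-Meier estimate at
    t. Groups whose follow-up ends before t get the KM value at the last
    observed time, flagged in the ``truncated`` column.
    """
    if n_groups < 2:
        raise ValidationError("n_groups must be >= 2")
    pi = np.asarray(predicted_survival, dtype=float)
    T = np.asarray(times, dtype=float)
    E = np.asarray(events, dtype=int)
    # rank-based grouping is stable under heavy ties (constant predictions
    # collapse to a single effective group)
    qs = np.quantile(pi, np.linspace(0, 1, n_groups + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    grp = np.clip(np.searchsorted(qs, pi, side="right") - 1, 0, n_groups - 1)
    rows = []
    for g in np.unique(grp):
        mask = grp == g
        u, s = km_estimate(T[mask], E[mask])
        t_eval = t
        truncated = False
        if T[mask].max() < t:
            t_eval = float(T[mask].max())
            truncated = True
        km = float(_km_at(u, s, t_eval)[0])
        rows.append(
            {
                "group": int(g),
                "n": int(mask.sum()),
                "mean_predicted": float(pi[mask].mean()),
                "km_observed": km,
                "truncated": truncated,
            }
        )
    return pd.DataFrame(rows)
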