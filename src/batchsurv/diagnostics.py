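"""Model-selection diagnostics beyond raw performance.

Three complementary views of a candidate strategy: (1) how *stable* its
variable selection is across training folds (Kuncheva index for
fixed-size selections, per-covariate selection frequencies otherwise);
(2) whether covariates that were deliberately left out of the candidate
set (e.g. to respect the events-per-variable rule) still carry residual
association with survival, via fold-averaged Martingale residuals; and
(3) whether the model's sensitivity/specificity at a fixed horizon depend
on an omitted covariate, via per-cutoff logistic regressions among the
dead-by-t and alive-after-t groups.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import SurvivalCohort
from .errors import ConfigurationError, ValidationError
from .resampling import CVResult

__all__ = [
    "kuncheva_index",
    "selection_frequency",
    "stability_report",
    "omitted_martingale",
    "omitted_sens_spec_models",
    "StabilityReport",
    "OmittedCovariateReport",
]


def kuncheva_index(set_a, set_b, n_candidates: int) -> float:
    """Chance-corrected overlap of two equal-size selected-feature sets.

    ``KI = (r - s^2/N) / (s - s^2/N)`` with ``s`` the common set size,
    ``r`` the overlap and ``N`` the candidate count. Equals 1 iff the sets
    are identical and 0 when the overlap is exactly the chance expectation.
    Undefined for s = N (every selection is the full set).
    """
    a, b = set(set_a), set(set_b)
    if len(a) != len(b):
        raise ValidationError("Kuncheva index requires equal-size sets")
    s = len(a)
    if s == 0 or s >= n_candidates:
        raise ValidationError("Kuncheva index undefined for s = 0 or s = N")
    r = len(a & b)
    expected = s * s / n_candidates
    return float((r - expected) / (s - expected))


def selection_frequency(cv: CVResult, candidates=None) -> pd.Series:
    """Fraction of (repetition, fold) fits in which each candidate covariate
    had a nonzero coefficient."""
    if candidates is None:
        candidates = (
            list(cv.strategy.candidates)
            if cv.strategy.candidates is not None
            else sorted({c for sel in cv.models["selected"] for c in sel})
        )
    n_fits = len(cv.models)
    counts = {c: 0 for c in candidates}
    for sel in cv.models["selected"]:
        for c in sel:
            if c in counts:
                counts[c] += 1
    freq = pd.Series(
        {c: counts[c] / n_fits if n_fits else 0.0 for c in candidates}, name="frequency"
    )
    return freq


@dataclass
class StabilityReport:
    """Selection stability across training folds."""

    pairwise: pd.DataFrame = field(repr=False, default=None)  # i, j, kuncheva
    mean_kuncheva: float = float("nan")
    frequencies: pd.Series = field(repr=False, default=None)


def stability_report(cv: CVResult, n_candidates: int | None = None) -> StabilityReport:
    """Kuncheva indices across all pairs of fits (only defined when all fits
    selected the same number of covariates) plus selection frequencies."""
    freqs = selection_frequency(cv)
    if n_candidates is None:
        n_candidates = (
            len(cv.strategy.candidates) if cv.strategy.candidates is not None else len(freqs)
        )
    sets = [tuple(sorted(s)) for s in cv.models["selected"]]
    sizes = {len(s) for s in sets}
    rows = []
    mean_ki = float("nan")
    if len(sizes) == 1 and sets:
        s = sizes.pop()
        if 0 < s < n_candidates:
            for (i, a), (j, b) in itertools.combinations(enumerate(sets), 2):
                rows.append({"i": i, "j": j, "kuncheva": kuncheva_index(a, b, n_candidates)})
            if rows:
                mean_ki = float(np.mean([r["kuncheva"] for r in rows]))
    return StabilityReport(
        pairwise=pd.DataFrame(rows), mean_kuncheva=mean_ki, frequencies=freqs
    )


@dataclass
class OmittedCovariateReport:
    """Impact of a covariate excluded from the candidate set."""

    omitted: str
    #: per-patient fold-averaged Martingale residuals joined to the covariate
    residuals: pd.DataFrame = field(repr=False, default=None)
    spearman_rho: float = float("nan")
    spearman_p: float = float("nan")
    #: (x, fitted) lowess-style smooth of residual vs covariate, plot-ready
    smooth: pd.DataFrame = field(repr=False, default=None)
    #: per (rep, cutoff): odds ratios and p-values of the logistic models
    logistic: pd.DataFrame = field(repr=False, default=None)
    #: per cutoff: proportion of p-values < 0.05
    flag_proportions: pd.DataFrame = field(repr=False, default=None)


def _check_omitted(cv: CVResult, cohort: SurvivalCohort, omitted: str) -> None:
    cand = (
        list(cv.strategy.candidates)
        if cv.strategy.candidates is not None
        else cohort.covariate_names
    )
    if omitted in cand:
        raise ConfigurationError(f"{omitted!r} is among the strategy's candidates")
    if omitted not in cohort.df.columns:
        raise ConfigurationError(f"{omitted!r} not present in the cohort")


def omitted_martingale(
    cohort: SurvivalCohort, cv: CVResult, omitted: str
) -> OmittedCovariateReport:
    """Residual association between survival and an omitted covariate.

    Martingale residuals from every training-fold fit are averaged per
    patient across all folds and repetitions in which the patient appeared
    in a training fold; the association with the omitted covariate is
    summarized by a Spearman rank correlation and a lowess smooth is
    exported for plotting.
    """
    _check_omitted(cv, cohort, omitted)
    avg = cv.residuals.groupby("patient_id")["martingale"].mean()
    cov = cohort.df.set_index("patient_id")[omitted].astype(float)
    joined = pd.DataFrame({"martingale": avg}).join(cov, how="inner")
    rho, p = stats.spearmanr(joined[omitted], joined["martingale"])
    lowess = sm.nonparametric.lowess(
        joined["martingale"].to_numpy(), joined[omitted].to_numpy(), frac=0.6
    )
    smooth = pd.DataFrame(lowess, columns=["x", "fitted"])
    return OmittedCovariateReport(
        omitted=omitted,
        residuals=joined.reset_index(),
        spearman_rho=float(rho),
        spearman_p=float(p),
        smooth=smooth,
    )


def _logit_or(y: np.ndarray, x: np.ndarray):
    """Logistic fit of y on x with intercept; returns (OR, p) or None when
    the cell is degenerate (single class or separation)."""
    if len(np.unique(y)) < 2:
        return None, "single-class response"
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        beta = res.params[1]
        p = res.pvalues[1]
        if not np.isfinite(p) or abs(beta) > 15:
            return None, "separation"
        return (float(np.exp(beta)), float(p)), None
    except Exception:  # noqa: BLE001 - perfect separation raises variously
        return None, "separation"


def omitted_sens_spec_models(
    cohort: SurvivalCohort,
    cv: CVResult,
    omitted: str,
    t: float,
    cutoffs=None,
) -> OmittedCovariateReport:
    """Per-cutoff logistic models testing whether sensitivity/specificity at
    time t depend on an omitted covariate.

    For each repetition (test-fold linear predictors pooled) and cutoff c:
    among patients dead by t, logistic regression of ``I(M > c)`` on the
    omitted covariate gives the sensitivity log-odds-ratio; among patients
    alive after t, ``I(M <= c)`` gives the specificity one. Patients
    censored before t are excluded (vital status unknown). Degenerate cells
    (single-class response, separation) are reported missing with a reason.
    Default cutoffs: inner deciles (10%..90%) of the pooled linear predictor.
    """
    _check_omitted(cv, cohort, omitted)
    scores = cv.scores.merge(
        cohort.df[["patient_id", omitted]], on="patient_id", how="left"
    )
    if cutoffs is None:
        cutoffs = np.quantile(scores["lp"], np.arange(0.1, 0.91, 0.1))
    rows = []
    for rep, rep_df in scores.groupby("rep"):
        known = rep_df[(rep_df["time"] > t) | (rep_df["event"] == 1)]
        dead = known[(known["time"] <= t) & (known["event"] == 1)]
        alive = known[known["time"] > t]
        for c in cutoffs:
            sens_val = float((dead["lp"] > c).mean()) if len(dead) else np.nan
            spec_val = float((alive["lp"] <= c).mean()) if len(alive) else np.nan
            for side, grp, resp in (
                ("sensitivity", dead, (dead["lp"] > c).astype(int) if len(dead) else None),
                ("specificity", alive, (alive["lp"] <= c).astype(int) if len(alive) else None),
            ):
                if resp is None or len(grp) < 3:
                    rows.append(
                        {
                            "rep": rep,
                            "cutoff": float(c),
                            "side": side,
                            "or_": np.nan,
                            "p": np.nan,
                            "reason": "too few patients",
                            "sens": sens_val,
                            "spec": spec_val,
                        }
                    )
                    continue
                out, reason = _logit_or(resp.to_numpy(), grp[omitted].to_numpy(dtype=float))
                rows.append(
                    {
                        "rep": rep,
                        "cutoff": float(c),
                        "side": side,
                        "or_": out[0] if out else np.nan,
                        "p": out[1] if out else np.nan,
                        "reason": reason,
                        "sens": sens_val,
                        "spec": spec_val,
                    }
                )
    logistic = pd.DataFrame(rows)
    flags = (
        logistic.dropna(subset=["p"])
        .assign(flag=lambda d: d["p"] < 0.05)
        .groupby(["cutoff", "side"])["flag"]
        .mean()
        .rename("prop_p_lt_05")
        .reset_index()
    )
    return OmittedCovariateReport(omitted=omitted, logistic=logistic, flag_proportions=flags)
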