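"""N-times k-fold cross-validation plans and execution.

Two fold-construction strategies are offered. Strategy A is the classical
outcome-stratified scheme: within each repetition, events and non-events
are shuffled separately and dealt round-robin, so per-fold event counts
differ by at most one. Strategy B respects the technical design: entire
batches are assigned to folds (a batch never splits across folds within a
repetition), greedily balancing patient counts; event proportions are then
*not* guaranteed equal across folds, which is exactly the feature that lets
batch-level resampling expose batch-driven optimism.

:func:`run_cv` re-runs the complete model-building recipe — selection,
functional form, fitting, shrinkage — inside every training fold; test-fold
patients only ever receive predictions from a model that never saw them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import SurvivalCohort
from .errors import ConfigurationError, ValidationError
from .metrics import c_index, td_auc, _surv_col
from .strategies import ModelStrategy, build_strategy_model

logger = logging.getLogger(__name__)

__all__ = ["FoldPlan", "CVResult", "make_folds_stratified", "make_folds_batchwise", "run_cv"]


@dataclass
class FoldPlan:
    """Assignment of train-role patients to test folds, per repetition."""

    strategy: str  # 'A' (patient-level stratified) or 'B' (batch-level)
    k: int
    n_rep: int
    seed: int
    #: columns: repetition, patient_id, fold
    assignment: pd.DataFrame = field(repr=False, default=None)

    def folds(self, rep: int) -> pd.Series:
        sub = self.assignment[self.assignment["repetition"] == rep]
        return sub.set_index("patient_id")["fold"]

    def to_csv(self, path) -> None:
        self.assignment.to_csv(path, index=False)


def _check_k(k: int):
    if k < 2:
        raise ConfigurationError("k must be >= 2")


def make_folds_stratified(
    cohort: SurvivalCohort, k: int, n_rep: int, seed: int
) -> FoldPlan:
    """Strategy A: patient-level, outcome-stratified folds.

    Events and non-events are shuffled separately and dealt round-robin into
    k folds (fold order re-permuted each repetition), so per-fold event
    counts differ by at most 1 within a repetition.
    """
    _check_k(k)
    train = cohort.train().df
    ids = train["patient_id"].to_numpy()
    ev = train["event"].to_numpy() == 1
    if ev.sum() < k or (~ev).sum() < k:
        raise ConfigurationError("need at least k events and k non-events to stratify")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_rep):
        fold_order = rng.permutation(k)
        for group in (ids[ev], ids[~ev]):
            shuffled = rng.permutation(group)
            for i, pid in enumerate(shuffled):
                rows.append((rep, pid, int(fold_order[i % k])))
    assignment = pd.DataFrame(rows, columns=["repetition", "patient_id", "fold"])
    return FoldPlan("A", k, n_rep, seed, assignment)


def make_folds_batchwise(
    cohort: SurvivalCohort, k: int, n_rep: int, seed: int
) -> FoldPlan:
    """Strategy B: batch-level folds.

    Batches are partitioned into k groups per repetition; all patients of a
    batch share one test-fold index. Patient counts are balanced greedily
    (largest batch first into the currently smallest fold; ties broken by
    the repetition's shuffled order).
    """
    _check_k(k)
    train = cohort.train().df
    sizes = train.groupby("batch")["patient_id"].size()
    if len(sizes) < k:
        raise ConfigurationError("fewer train batches than folds")
    rng = np.random.default_rng(seed)
    batch_names = np.array(sizes.index)
    rows = []
    for rep in range(n_rep):
        order = rng.permutation(len(batch_names))
        shuffled = batch_names[order]
        # stable sort by size desc keeps the shuffled order among ties
        by_size = sorted(shuffled, key=lambda b: -sizes[b])
        totals = np.zeros(k, dtype=int)
        fold_of: dict[str, int] = {}
        tie_break = rng.permutation(k)
        for b in by_size:
            # smallest fold; ties resolved by the repetition's permutation
            f = min(range(k), key=lambda j: (totals[j], tie_break[j]))
            fold_of[b] = f
            totals[f] += sizes[b]
        for pid, b in zip(train["patient_id"], train["batch"]):
            rows.append((rep, pid, fold_of[b]))
    assignment = pd.DataFrame(rows, columns=["repetition", "patient_id", "fold"])
    return FoldPlan("B", k, n_rep, seed, assignment)


@dataclass
class CVResult:
    """Everything the downstream performance/diagnostic layers need.

    ``scores``: one row per (rep, fold, test patient) with the linear
    predictor and predicted survival at the evaluation times. ``models``:
    per-fit selected set and coefficients. ``apparent``: training-fold
    indicators recorded at fit time. ``residuals``: per-fit Martingale
    residuals of training-fold patients.
    """

    plan: FoldPlan
    strategy: ModelStrategy
    time_grid: list
    scores: pd.DataFrame = field(repr=False, default=None)
    models: pd.DataFrame = field(repr=False, default=None)
    apparent: pd.DataFrame = field(repr=False, default=None)
    residuals: pd.DataFrame = field(repr=False, default=None)
    skipped: list = field(default_factory=list)

    def selected_sets(self) -> list[tuple[int, int, tuple]]:
        return [
            (r.rep, r.fold, tuple(r.selected)) for r in self.models.itertuples()
        ]


def run_cv(
    cohort: SurvivalCohort,
    plan: FoldPlan,
    strategy: ModelStrategy,
    time_grid,
) -> CVResult:
    """Execute the full model-building pipeline inside each training fold.

    For every (repetition, fold): the entire strategy is re-run on the
    training fold only; test-fold patients receive linear predictors and
    predicted survivals from the training-fold model; apparent indicators
    (AUC at each grid time, C-index) are computed on the training fold.
    Folds whose training part has zero events are skipped and logged.
    """
    train = cohort.train().df.set_index("patient_id", drop=False)
    plan_ids = set(plan.assignment["patient_id"])
    if plan_ids != set(train.index):
        raise ValidationError("fold plan does not match the cohort's train patients")
    time_grid = [float(t) for t in np.atleast_1d(time_grid)]
    cand = (
        list(strategy.candidates)
        if strategy.candidates is not None
        else cohort.covariate_names
    )

    score_rows, model_rows, app_rows, resid_rows = [], [], [], []
    skipped = []
    for rep in range(plan.n_rep):
        folds = plan.folds(rep)
        for f in range(plan.k):
            test_ids = folds.index[folds == f]
            train_ids = folds.index[folds != f]
            tr = train.loc[train_ids]
            te = train.loc[test_ids]
            if tr["event"].sum() == 0:
                logger.warning("rep %d fold %d skipped: no events in training fold", rep, f)
                skipped.append((rep, f, "no events in training fold"))
                continue
            try:
                sfit = build_strategy_model(
                    strategy, tr["time"].to_numpy(), tr["event"].to_numpy(), tr[cand]
                )
            except Exception as exc:  # noqa: BLE001 - recorded, not silenced
                logger.warning("rep %d fold %d skipped: %s", rep, f, exc)
                skipped.append((rep, f, str(exc)))
                continue
            lp_te = sfit.linear_predictor(te[cand])
            surv_te = sfit.predict_survival(te[cand], time_grid)
            for i, pid in enumerate(test_ids):
                row = {
                    "rep": rep,
                    "fold": f,
                    "patient_id": pid,
                    "time": float(te.loc[pid, "time"]),
                    "event": int(te.loc[pid, "event"]),
                    "lp": float(lp_te[i]),
                }
                for j, t in enumerate(time_grid):
                    row[_surv_col(t)] = float(surv_te[i, j])
                score_rows.append(row)
            model_rows.append(
                {
                    "rep": rep,
                    "fold": f,
                    "selected": list(sfit.selected),
                    "coefficients": dict(sfit.results.params),
                }
            )
            # apparent indicators on the training fold
            lp_tr = sfit.linear_predictor(tr[cand])
            t_tr = tr["time"].to_numpy()
            e_tr = tr["event"].to_numpy()
            for t in time_grid:
                try:
                    val = td_auc(lp_tr, t_tr, e_tr, t)
                except ValidationError:
                    val = np.nan
                app_rows.append(
                    {"rep": rep, "fold": f, "indicator": "td_auc", "time": t, "value": val}
                )
            try:
                cval = c_index(lp_tr, t_tr, e_tr)
            except ValidationError:
                cval = np.nan
            app_rows.append(
                {"rep": rep, "fold": f, "indicator": "c_index", "time": np.nan, "value": cval}
            )
            mres = sfit.results.martingale_residuals()
            for pid, m in zip(train_ids, mres):
                resid_rows.append(
                    {"rep": rep, "fold": f, "patient_id": pid, "martingale": float(m)}
                )

    return CVResult(
        plan=plan,
        strategy=strategy,
        time_grid=time_grid,
        scores=pd.DataFrame(score_rows),
        models=pd.DataFrame(model_rows),
        apparent=pd.DataFrame(app_rows),
        residuals=pd.DataFrame(resid_rows),
        skipped=skipped,
    )
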