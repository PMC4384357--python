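"""Config-driven orchestration: generate-or-load a cohort, cross-validate a
set of model-building strategies under both resampling schemes, compute
performance and diagnostic reports, shortlist, fit the final model and
validate it on the independent test set.

Every report is a plain CSV/JSON artifact in the output directory; a
structured log records every skipped fold or degenerate cell with its
(strategy, repetition, fold) coordinate. All randomness is expanded
deterministically from one master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CovariateSpec, SurvivalCohort, read_cohort, write_cohort
from .diagnostics import omitted_martingale, omitted_sens_spec_models, stability_report
from .errors import ConfigurationError
from .metrics import aggregate_cv, optimism
from .resampling import make_folds_batchwise, make_folds_stratified, run_cv
from .simulate import GeneratorConfig, generate_cohort
from .strategies import ModelStrategy
from .validation import bootstrap_ci, final_fit, hazard_ratio_table, validate_on_test

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "shortlist"]


@dataclass
class RunConfig:
    """Pipeline configuration (YAML-serializable)."""

    cohort_path: str | None = None
    generator: dict | None = None
    covariate_specs: list = field(default_factory=list)  # dicts for CovariateSpec
    strategies: list = field(default_factory=list)  # dicts for ModelStrategy
    k: int = 5
    n_rep: int = 20
    resampling: tuple[str, ...] = ("A", "B")
    eval_times: tuple[float, ...] = (7.0,)
    primary_time: float = 7.0
    omitted: tuple[str, ...] = ()
    seed: int = 0
    out_dir: str = "batchsurv_out"
    shortlist_tolerance: float = 0.02
    bootstrap_B: int = 200
    #: opinion-driven covariates of clinical interest; affects ranking notes only
    clinical_whitelist: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.strategies:
            raise ConfigurationError("at least one model strategy is required")
        if self.cohort_path is None and self.generator is None:
            raise ConfigurationError("either cohort_path or generator must be given")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("resampling", "eval_times", "omitted", "clinical_whitelist"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def model_strategies(self) -> list[ModelStrategy]:
        return [ModelStrategy.from_dict(d) for d in self.strategies]

    def specs(self) -> list[CovariateSpec]:
        return [CovariateSpec(**d) for d in self.covariate_specs]


def _load_cohort(config: RunConfig) -> SurvivalCohort:
    if config.cohort_path is not None:
        return read_cohort(config.cohort_path, config.specs())
    gen = GeneratorConfig(**{**config.generator, "seed": config.generator.get("seed", config.seed)})
    cohort, _ = generate_cohort(gen)
    from .cohort import dichotomize

    if config.covariate_specs:
        cohort = dichotomize(cohort, config.specs())
    return cohort


def _fold_seed(master: int, strategy_label: str) -> int:
    child = np.random.SeedSequence(master, spawn_key=(ord(strategy_label),))
    return int(child.generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: RunConfig) -> Path:
    """Run the full workflow; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("batchsurv")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> Path:
    cohort = _load_cohort(config)
    write_cohort(cohort, out / "cohort.csv")
    strategies = config.model_strategies()
    plans = {}
    for label in config.resampling:
        seed = _fold_seed(config.seed, label)
        maker = make_folds_stratified if label == "A" else make_folds_batchwise
        plans[label] = maker(cohort, config.k, config.n_rep, seed)
        plans[label].to_csv(out / f"folds_{label}.csv")

    perf_rows, freq_rows, opt_rows = [], [], []
    cv_store = {}
    for strat in strategies:
        for label, plan in plans.items():
            logger.info("CV: strategy=%s resampling=%s", strat.name, label)
            cv = run_cv(cohort, plan, strat, config.eval_times)
            cv_store[(strat.name, label)] = cv
            for (agg, score) in (
                ("pooled", "linear_predictor"),
                ("pooled", "predicted_survival"),
                ("averaged", "linear_predictor"),
                ("averaged", "predicted_survival"),
            ):
                for ind in ("td_auc", "c_index"):
                    if ind == "c_index" and score == "predicted_survival":
                        continue
                    import warnings as _w

                    with _w.catch_warnings():
                        _w.simplefilter("ignore")
                        est = aggregate_cv(cv, ind, score, agg, config.eval_times)
                    for t, v in zip(est.times, est.values):
                        perf_rows.append(
                            {
                                "model": strat.name,
                                "resampling": label,
                                "indicator": ind,
                                "aggregation": agg,
                                "score_type": score,
                                "time": t,
                                "value": v,
                            }
                        )
            freqs = stability_report(cv)
            for cov, fr in freqs.frequencies.items():
                freq_rows.append(
                    {
                        "model": strat.name,
                        "resampling": label,
                        "covariate": cov,
                        "frequency": fr,
                        "mean_kuncheva": freqs.mean_kuncheva,
                    }
                )
            opt = optimism(cv, "td_auc", config.eval_times)
            for r in opt.itertuples():
                opt_rows.append(
                    {
                        "model": strat.name,
                        "resampling": label,
                        "time": r.time,
                        "apparent": r.apparent,
                        "validated": r.validated,
                        "optimism": r.optimism,
                    }
                )
            for rep, fold, reason in cv.skipped:
                logger.warning(
                    "skipped: strategy=%s resampling=%s rep=%d fold=%d: %s",
                    strat.name,
                    label,
                    rep,
                    fold,
                    reason,
                )

    perf = pd.DataFrame(perf_rows)
    perf.to_csv(out / "performance.csv", index=False)
    pd.DataFrame(freq_rows).to_csv(out / "selection_frequency.csv", index=False)
    opt_df = pd.DataFrame(opt_rows)
    opt_df.to_csv(out / "optimism.csv", index=False)

    ranked = shortlist(
        perf,
        pd.DataFrame(freq_rows),
        opt_df,
        strategies,
        primary_time=config.primary_time,
        tolerance=config.shortlist_tolerance,
        clinical_whitelist=config.clinical_whitelist,
    )
    ranked.to_csv(out / "shortlist.csv", index=False)
    top_name = ranked["model"].iloc[0]
    top = next(s for s in strategies if s.name == top_name)
    logger.info("shortlisted model: %s", top_name)

    # omitted-covariate diagnostics for the retained model (strategy B CV)
    label = "B" if "B" in plans else list(plans)[0]
    cv_top = cv_store[(top_name, label)]
    for cov in config.omitted:
        rep_m = omitted_martingale(cohort, cv_top, cov)
        rep_m.residuals.to_csv(out / f"omitted_{cov}_martingale.csv", index=False)
        rep_m.smooth.to_csv(out / f"omitted_{cov}_smooth.csv", index=False)
        rep_l = omitted_sens_spec_models(cohort, cv_top, cov, config.primary_time)
        rep_l.logistic.to_csv(out / f"omitted_{cov}_logistic.csv", index=False)
        rep_l.flag_proportions.to_csv(out / f"omitted_{cov}_flags.csv", index=False)

    # final fit + independent validation
    sfit = final_fit(cohort, top)
    hazard_ratio_table(sfit).to_csv(out / "final_model_hr.csv")
    report = validate_on_test(sfit, cohort, time_grid=config.eval_times)
    report.curves.to_csv(out / "test_performance.csv", index=False)
    ci = bootstrap_ci(
        sfit,
        cohort,
        "td_auc",
        config.eval_times,
        B=config.bootstrap_B,
        seed=_fold_seed(config.seed, "b"),
    )
    ci.to_csv(out / "test_bootstrap_ci.csv", index=False)

    meta = {
        "seed": config.seed,
        "k": config.k,
        "n_rep": config.n_rep,
        "resampling": list(config.resampling),
        "eval_times": [float(t) for t in config.eval_times],
        "strategies": [s.name for s in strategies],
        "shortlisted": top_name,
        "fold_seeds": {label: _fold_seed(config.seed, label) for label in config.resampling},
    }
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return out


def _family(strategy: ModelStrategy) -> str:
    fam = strategy.selection
    if strategy.refit_unpenalized:
        fam += "+refit"
    return fam


def _complexity(strategy: ModelStrategy, freq: pd.DataFrame) -> float:
    sub = freq[freq["model"] == strategy.name]
    if sub.empty:
        return 0.0
    return float(np.round(sub["frequency"].sum()))


def shortlist(
    perf: pd.DataFrame,
    freq: pd.DataFrame,
    opt: pd.DataFrame,
    strategies: list[ModelStrategy],
    primary_time: float = 7.0,
    tolerance: float = 0.02,
    resampling: str | None = None,
    clinical_whitelist=(),
) -> pd.DataFrame:
    """Rank candidate models: keep those within ``tolerance`` of the best
    primary indicator (batch-level pooled linear-predictor AUC at the
    primary time — the most conservative estimation scheme), then rank by
    higher stability, lower optimism; retain at most one model per
    (selection family, complexity level).
    """
    if resampling is None:
        resampling = "B" if (perf["resampling"] == "B").any() else perf["resampling"].iloc[0]
    primary = perf[
        (perf["resampling"] == resampling)
        & (perf["indicator"] == "td_auc")
        & (perf["aggregation"] == "pooled")
        & (perf["score_type"] == "linear_predictor")
        & (np.isclose(perf["time"], primary_time))
    ].set_index("model")["value"]
    if primary.empty:
        raise ConfigurationError("no models with a primary indicator value")
    best = primary.max()
    keep = primary[primary >= best - tolerance]
    strat_by_name = {s.name: s for s in strategies}
    rows = []
    for name, auc in keep.items():
        strat = strat_by_name[name]
        sub_f = freq[(freq["model"] == name) & (freq["resampling"] == resampling)]
        stability = (
            float(sub_f["mean_kuncheva"].iloc[0])
            if len(sub_f) and np.isfinite(sub_f["mean_kuncheva"].iloc[0])
            else float(np.mean(np.abs(sub_f["frequency"] - 0.5)) * 2) if len(sub_f) else 0.0
        )
        sub_o = opt[
            (opt["model"] == name)
            & (opt["resampling"] == resampling)
            & (np.isclose(opt["time"], primary_time))
        ]
        opti = float(sub_o["optimism"].iloc[0]) if len(sub_o) else np.nan
        selected_often = sub_f[sub_f["frequency"] >= 0.5]["covariate"].tolist()
        note = (
            "includes clinical-interest covariate(s): "
            + ",".join(sorted(set(selected_often) & set(clinical_whitelist)))
            if set(selected_often) & set(clinical_whitelist)
            else ""
        )
        rows.append(
            {
                "model": name,
                "family": _family(strat),
                "complexity": _complexity(strat, sub_f),
                "primary_auc": float(auc),
                "stability": stability,
                "optimism": opti,
                "note": note,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["stability", "optimism", "primary_auc"],
        ascending=[False, True, False],
        kind="stable",
    )
    # one model per (family, complexity)
    df = df.drop_duplicates(subset=["family", "complexity"], keep="first")
    return df.reset_index(drop=True)
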