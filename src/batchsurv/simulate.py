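"""Synthetic batch-structured RT-qPCR survival cohorts with known truth.

The generator emulates a multi-centric septic-shock style study: 156
training and 95 test patients, processed over 14 + 9 PCR batches, with
roughly 28% death events by the day-14 administrative censoring horizon and
event proportions that vary from batch to batch.

Mechanics: patients get a biological gene-expression signal (standard
normal on the ΔCt scale) plus an additive batch-level technical shift
shared by all genes within a batch (scaled by a per-gene loading), plus
measurement noise; clinical covariates are batch-free. Event times come by
inverse transform from a Weibull-baseline proportional-hazards law
``S(t|Z) = exp(-(t/scale)^shape * exp(Z beta))`` where ``Z`` is the
*biological* signal — the technical shift perturbs the measurement, not the
hazard. Batch-to-batch outcome imbalance is induced by a per-batch
log-normal frailty multiplier on the hazard; its log-scale SD is the
``batch_event_dispersion`` knob. The baseline scale is calibrated by root
finding so that the expected event proportion at the censoring horizon
matches ``target_event_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import SurvivalCohort
from .errors import ConfigurationError, FormatError

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_cohort",
    "normalize_delta_ct",
    "batch_event_summary",
]


@dataclass
class GeneratorConfig:
    """Study-design parameters for cohort generation.

    Defaults reproduce the reference study design: 156/95 train/test
    patients over 14/9 batches, ~28% events by day 14. ``batch_sd`` (Ct
    units) and ``batch_event_dispersion`` (SD of the per-batch log frailty)
    have no empirical anchor and are documented as modelling choices.
    """

    n_train: int = 156
    n_test: int = 95
    n_batches_train: int = 14
    n_batches_test: int = 9
    n_genes: int = 6
    n_clinical: int = 3
    beta_true: tuple[float, ...] = (0.5, -0.45, 0.4, 0.0, 0.0, 0.0, 0.45, 0.35, 0.0)
    baseline_shape: float = 1.2
    baseline_scale: float | None = None  # None -> calibrated to target_event_rate
    batch_sd: float = 0.5
    batch_event_dispersion: float = 0.5
    censor_time: float = 14.0
    target_event_rate: float = 0.28
    dropout_rate: float = 0.0  # optional uniform early dropout, off by default
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_train,
            self.n_test,
            self.n_batches_train,
            self.n_batches_test,
            self.n_genes,
            self.n_clinical,
        )
        if any(c <= 0 for c in counts):
            raise ConfigurationError("all counts must be positive")
        if self.n_batches_train > self.n_train or self.n_batches_test > self.n_test:
            raise ConfigurationError("more batches than patients")
        if self.batch_sd < 0:
            raise ConfigurationError("batch_sd must be >= 0")
        if not (0 < self.target_event_rate < 1):
            raise ConfigurationError("target_event_rate must be in (0,1)")
        if self.censor_time <= 0:
            raise ConfigurationError("censor_time must be positive")
        p = self.n_genes + self.n_clinical
        if len(self.beta_true) != p:
            raise ConfigurationError(
                f"beta_true must have length n_genes + n_clinical = {p}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would not."""

    beta_true: np.ndarray
    batch_shifts: pd.Series  # technical shift per batch (Ct units)
    batch_frailty: pd.Series  # log hazard multiplier per batch
    gene_loadings: np.ndarray
    linear_predictor: np.ndarray  # biological Z_signal @ beta per patient
    uncensored_times: np.ndarray
    baseline_scale: float
    baseline_shape: float


def _batch_sizes(n: int, k: int) -> np.ndarray:
    base = n // k
    sizes = np.full(k, base, dtype=int)
    sizes[: n - base * k] += 1
    return sizes


def _calibrate_scale(cfg: GeneratorConfig, eta: np.ndarray) -> float:
    """Solve for the Weibull scale giving the target expected event rate at
    the censoring horizon, given the realized per-patient log hazards."""

    def rate(scale):
        surv = np.exp(-((cfg.censor_time / scale) ** cfg.baseline_shape) * np.exp(eta))
        return float(1.0 - surv.mean())

    lo, hi = 1e-3, 1e9
    target = cfg.target_event_rate
    if rate(lo) < target or rate(hi) > target:  # pragma: no cover
        raise ConfigurationError("cannot calibrate baseline scale to target rate")
    return brentq(lambda s: rate(s) - target, lo, hi, xtol=1e-8, rtol=1e-10)


def generate_cohort(cfg: GeneratorConfig) -> tuple[SurvivalCohort, GroundTruth]:
    """Generate a batch-structured survival cohort and its ground truth.

    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_train + cfg.n_test
    k = cfg.n_batches_train + cfg.n_batches_test
    p = cfg.n_genes + cfg.n_clinical

    # batch membership: sizes as equal as possible within each role
    batches = []
    roles = []
    for role, n_role, k_role, offset in (
        ("train", cfg.n_train, cfg.n_batches_train, 0),
        ("test", cfg.n_test, cfg.n_batches_test, cfg.n_batches_train),
    ):
        sizes = _batch_sizes(n_role, k_role)
        for b, size in enumerate(sizes):
            batches.extend([f"B{offset + b + 1:02d}"] * size)
            roles.extend([role] * size)
    batches = np.array(batches)
    roles = np.array(roles)
    batch_labels = [f"B{i + 1:02d}" for i in range(k)]

    # covariates: biological signal + technical batch shift + noise
    signal = rng.standard_normal((n, p))
    shifts = pd.Series(rng.normal(0.0, cfg.batch_sd, size=k), index=batch_labels)
    loadings = rng.uniform(0.5, 1.5, size=cfg.n_genes)
    observed = signal.copy()
    shift_per_patient = shifts.loc[batches].to_numpy()
    for g in range(cfg.n_genes):
        observed[:, g] += loadings[g] * shift_per_patient
        observed[:, g] += rng.normal(0.0, cfg.noise_sd, size=n)
    # clinical covariates are batch-free (no shift, no extra noise)

    beta = np.asarray(cfg.beta_true, dtype=float)
    lp = signal @ beta
    frailty = pd.Series(
        rng.normal(0.0, cfg.batch_event_dispersion, size=k), index=batch_labels
    )
    eta = lp + frailty.loc[batches].to_numpy()

    scale = cfg.baseline_scale
    if scale is None:
        scale = _calibrate_scale(cfg, eta)

    # inverse-transform sampling from S(t|Z) = exp(-(t/scale)^shape e^eta)
    u = rng.uniform(size=n)
    t_event = scale * (-np.log(u) / np.exp(eta)) ** (1.0 / cfg.baseline_shape)

    t_obs = np.minimum(t_event, cfg.censor_time)
    event = (t_event <= cfg.censor_time).astype(int)
    if cfg.dropout_rate > 0:
        drop = rng.uniform(size=n) < cfg.dropout_rate
        t_drop = rng.uniform(0.0, cfg.censor_time, size=n)
        early = drop & (t_drop < t_obs)
        t_obs = np.where(early, t_drop, t_obs)
        event = np.where(early, 0, event)

    gene_names = [f"G{i + 1}" for i in range(cfg.n_genes)]
    clin_names = [f"C{i + 1}" for i in range(cfg.n_clinical)]
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n)],
            "time": np.round(t_obs, 6),
            "event": event,
            "batch": batches,
            "role": roles,
        }
    )
    for j, name in enumerate(gene_names + clin_names):
        df[name] = np.round(observed[:, j], 6)
    kinds = {g: "gene" for g in gene_names}
    kinds.update({c: "clinical_continuous" for c in clin_names})

    cohort = SurvivalCohort(df, kinds)
    truth = GroundTruth(
        beta_true=beta,
        batch_shifts=shifts,
        batch_frailty=frailty,
        gene_loadings=loadings,
        linear_predictor=lp,
        uncensored_times=t_event,
        baseline_scale=float(scale),
        baseline_shape=cfg.baseline_shape,
    )
    return cohort, truth


def normalize_delta_ct(raw_ct: pd.DataFrame, reference: str) -> pd.DataFrame:
    """ΔCt normalization against a single reference (housekeeping) gene.

    Each entry becomes ``Ct_gene - Ct_reference`` per patient (row); the
    reference column is removed. Adding a patient-level constant to all Ct
    values leaves the result unchanged.
    """
    if reference not in raw_ct.columns:
        raise FormatError(f"reference gene {reference!r} not in matrix")
    ref = raw_ct[reference]
    out = raw_ct.drop(columns=[reference]).sub(ref, axis=0)
    return out


def batch_event_summary(cohort: SurvivalCohort) -> pd.DataFrame:
    """Per-batch event proportions with a summary row (mean and IQR)."""
    g = cohort.df.groupby("batch", sort=True)["event"]
    tab = pd.DataFrame(
        {"n": g.size(), "events": g.sum(), "proportion": g.mean()}
    ).reset_index()
    props = tab["proportion"]
    q1, q3 = props.quantile([0.25, 0.75])
    summary = pd.DataFrame(
        {
            "batch": ["<all>"],
            "n": [int(tab["n"].sum())],
            "events": [int(tab["events"].sum())],
            "proportion": [props.mean()],
            "q1": [q1],
            "q3": [q3],
        }
    )
    tab["q1"] = np.nan
    tab["q3"] = np.nan
    return pd.concat([tab, summary], ignore_index=True)
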