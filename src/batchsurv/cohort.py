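"""Cohort data structures and delimited-text I/O.

A cohort is one row per patient: identifier, follow-up time in days, a 0/1
death indicator, the technical batch (PCR plate / RT run) the sample was
processed in, the dataset role (``train`` or ``test``), and one column per
candidate covariate. Gene-expression covariates are on the normalized Ct
(ΔCt) scale; clinical covariates are continuous or binary.

A batch is never split across the train and test roles: the batch is the
unit of technical variability, and the whole point of the downstream
batch-level resampling is that train and test material were processed on
different plates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

REQUIRED_COLUMNS = ("patient_id", "time", "event", "batch", "role")
ROLES = ("train", "test")
COVARIATE_KINDS = ("gene", "clinical_continuous", "clinical_binary")

#: printed precision for covariate/time values in cohort files; chosen so
#: that write -> read round-trips are exact for values produced here.
_FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class CovariateSpec:
    """Declaration of one candidate covariate.

    Parameters
    ----------
    name : str
        Column name in the cohort file.
    kind : str
        One of ``gene``, ``clinical_continuous``, ``clinical_binary``.
    dichotomize_at : float, optional
        Expert cutoff: if given (only legal for continuous clinical
        covariates) a companion binary column ``<name>_Fac`` is appended on
        read, coded 1 when the raw value exceeds the cutoff.
    """

    name: str
    kind: str
    dichotomize_at: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in COVARIATE_KINDS:
            raise ValidationError(f"unknown covariate kind {self.kind!r}")
        if self.dichotomize_at is not None and self.kind != "clinical_continuous":
            raise ValidationError(
                f"dichotomize_at only applies to clinical_continuous covariates, "
                f"not {self.kind!r} ({self.name})"
            )


@dataclass
class SurvivalCohort:
    """Patient-level survival table with batch structure.

    Attributes
    ----------
    df : pandas.DataFrame
        Columns ``patient_id, time, event, batch, role`` plus one column per
        covariate, in deterministic order.
    covariate_kinds : dict
        Maps covariate name -> kind tag.
    """

    df: pd.DataFrame
    covariate_kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        df = self.df
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"missing required column {col!r}")
        if df["patient_id"].duplicated().any():
            raise ValidationError("duplicate patient_id values")
        for col in ("time", "event", "batch"):
            if df[col].isna().any():
                raise ValidationError(f"missing values in {col!r}")
        if (df["time"] < 0).any():
            raise ValidationError("negative follow-up time")
        if not df["event"].isin([0, 1]).all():
            raise ValidationError("event indicator must be 0 or 1")
        bad_roles = set(df["role"].unique()) - set(ROLES)
        if bad_roles:
            raise ValidationError(f"unknown roles {sorted(bad_roles)}")
        roles_per_batch = df.groupby("batch", sort=False)["role"].nunique()
        split = roles_per_batch[roles_per_batch > 1]
        if len(split):
            raise ValidationError(
                f"batch(es) {list(split.index)} span both train and test roles"
            )
        for name in self.covariate_kinds:
            if name not in df.columns:
                raise ValidationError(f"declared covariate {name!r} not in table")

    # -- accessors ------------------------------------------------------
    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariate_kinds)

    @property
    def n_patients(self) -> int:
        return len(self.df)

    @property
    def n_events(self) -> int:
        return int(self.df["event"].sum())

    def subset(self, mask) -> "SurvivalCohort":
        sub = self.df.loc[mask].reset_index(drop=True)
        return SurvivalCohort(sub, dict(self.covariate_kinds))

    def train(self) -> "SurvivalCohort":
        return self.subset(self.df["role"] == "train")

    def test(self) -> "SurvivalCohort":
        return self.subset(self.df["role"] == "test")

    def times(self) -> np.ndarray:
        return self.df["time"].to_numpy(dtype=float)

    def events(self) -> np.ndarray:
        return self.df["event"].to_numpy(dtype=int)

    def Z(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        """Covariate matrix (patients x covariates)."""
        if names is None:
            names = self.covariate_names
        return self.df[list(names)].astype(float)

    def check_candidates(self, names: Iterable[str]) -> None:
        """Reject constant columns among candidates offered to model building."""
        for name in names:
            col = self.df[name].to_numpy(dtype=float)
            if np.ptp(col) == 0:
                raise ValidationError(f"candidate covariate {name!r} is constant")

    def equals(self, other: "SurvivalCohort") -> bool:
        return self.df.equals(other.df) and self.covariate_kinds == other.covariate_kinds


def dichotomize(cohort: SurvivalCohort, specs: Sequence[CovariateSpec]) -> SurvivalCohort:
    """Append ``<name>_Fac`` companion columns for specs with a cutoff.

    Idempotent: an existing ``<name>_Fac`` column is recomputed, never
    duplicated. Row count is preserved.
    """
    df = cohort.df.copy()
    kinds = dict(cohort.covariate_kinds)
    for spec in specs:
        if spec.dichotomize_at is None:
            continue
        if spec.name not in df.columns:
            raise FormatError(f"covariate {spec.name!r} not in cohort")
        fac = f"{spec.name}_Fac"
        df[fac] = (df[spec.name].astype(float) > spec.dichotomize_at).astype(float)
        kinds[fac] = "clinical_binary"
    return SurvivalCohort(df, kinds)


def _infer_kinds(columns: Sequence[str], specs: Sequence[CovariateSpec] | None) -> dict[str, str]:
    declared = {s.name: s.kind for s in specs} if specs else {}
    kinds: dict[str, str] = {}
    for col in columns:
        if col in REQUIRED_COLUMNS:
            continue
        kinds[col] = declared.get(col, "clinical_continuous")
    return kinds


def read_cohort(path, specs: Sequence[CovariateSpec] | None = None) -> SurvivalCohort:
    """Read a CSV cohort file and validate it.

    The file must have a header with ``patient_id,time,event,batch,role`` and
    one column per covariate. Covariates named in ``specs`` get their declared
    kind; undeclared ones default to ``clinical_continuous``. Specs with a
    ``dichotomize_at`` cutoff get a companion ``<name>_Fac`` binary column.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "batch": str, "role": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"cohort file missing required column {col!r}")
    df["time"] = pd.to_numeric(df["time"], errors="raise")
    df["event"] = pd.to_numeric(df["event"], errors="raise")
    kinds = _infer_kinds(df.columns, specs)
    cohort = SurvivalCohort(df, kinds)
    if specs:
        cohort = dichotomize(cohort, specs)
    return cohort


def write_cohort(cohort: SurvivalCohort, path) -> None:
    """Write a cohort as CSV, re-readable by :func:`read_cohort`.

    Column order is deterministic: the five required columns, then
    covariates in declaration order.
    """
    cols = list(REQUIRED_COLUMNS) + cohort.covariate_names
    out = cohort.df[cols]
    buf = io.StringIO()
    out.to_csv(buf, index=False, float_format=_FLOAT_FORMAT)
    text = buf.getvalue()
    with open(path, "w", newline="") as fh:
        fh.write(text)
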