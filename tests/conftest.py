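import numpy as np
import pandas as pd
import pytest

from batchsurv import GeneratorConfig, generate_cohort
from batchsurv.cohort import SurvivalCohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-design synthetic cohort shared by read-only tests."""
    cohort, truth = generate_cohort(GeneratorConfig(seed=42))
    return cohort, truth


@pytest.fixture()
def toy6():
    """Six patients, distinct times, all events, binary covariate."""
    T = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    E = np.ones(6, dtype=int)
    Z = pd.DataFrame({"z": [1.0, 1.0, 0.0, 1.0, 0.0, 0.0]})
    return T, E, Z


def make_cohort_df(times, events, batches, roles, **covs):
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(len(times))],
            "time": times,
            "event": events,
            "batch": batches,
            "role": roles,
        }
    )
    for name, vals in covs.items():
        df[name] = vals
    return df


@pytest.fixture()
def tiny_cohort():
    df = make_cohort_df(
        [2.0, 5.0, 7.0, 14.0],
        [1, 1, 0, 0],
        ["B1", "B1", "B2", "B2"],
        ["train"] * 4,
        G1=[0.1, -0.3, 1.2, 0.4],
    )
    return SurvivalCohort(df, {"G1": "gene"})
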