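import numpy as np
import pandas as pd
import pytest

from gofsurv import CohortConfig, SurvivalData, assemble_cohort


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig(seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """One N=2000 cohort at the default 5% event rate (calibrated once)."""
    return assemble_cohort(CohortConfig(seed=42))


def make_survival_data(rng, n=40, p=3, weighted=True, censor=0.3):
    """Random small right-censored dataset with positive weights."""
    X = rng.standard_normal((n, p))
    beta = rng.uniform(-0.8, 0.8, p)
    t = rng.exponential(np.exp(-X @ beta))
    e = (rng.random(n) > censor).astype(float)
    e[rng.integers(0, n)] = 1.0  # guarantee an event
    w = rng.uniform(0.5, 3.0, n) if weighted else np.ones(n)
    return SurvivalData(t, e, X, w, names=[f"x{j}" for j in range(p)])


def as_dataframe(data: SurvivalData) -> pd.DataFrame:
    df = pd.DataFrame(data.covariates, columns=data.names)
    df["time"] = data.time
    df["event"] = data.event
    df["w"] = data.weights
    return df
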