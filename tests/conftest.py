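"""Shared fixtures: deterministic synthetic cohorts and model specs."""
import numpy as np
import pandas as pd
import pytest

from polymediate import MediationSpec, SimulationConfig, simulate_cohort
from polymediate.simulate import Covariate

FULL_COVARIATES = (
    Covariate("sex", "binary", prevalence=0.6, beta_mediator=0.05, beta_outcome=0.10),
    Covariate("age", "continuous", beta_mediator=0.05, beta_outcome=0.10),
    Covariate("smoking", "binary", prevalence=0.08, beta_mediator=0.05, beta_outcome=0.05),
    Covariate("ethnicity", "binary", prevalence=0.01),
    Covariate("depression", "continuous", beta_mediator=0.10, beta_outcome=0.10),
    Covariate("anxiety", "continuous", beta_mediator=0.05, beta_outcome=0.05),
)


@pytest.fixture(scope="session")
def default_cohort():
    """One medium cohort under the default generating paths."""
    return simulate_cohort(SimulationConfig(n_individuals=3000, n_variants=50, seed=101))


@pytest.fixture(scope="session")
def spec_age_sex():
    return MediationSpec(
        exposure="zgrs",
        mediator="disinhibition",
        outcome="bmi",
        covariates_a=("age", "sex"),
        covariates_b=("age", "sex"),
    )


@pytest.fixture()
def random_linear_data():
    """Generic random data with a genuine mediation structure, no covariates."""
    rng = np.random.default_rng(7)
    n = 400
    x = rng.normal(size=n)
    c1 = rng.binomial(1, 0.4, size=n).astype(float)
    c2 = rng.normal(size=n)
    m = 0.3 * x + 0.2 * c1 - 0.1 * c2 + rng.normal(size=n)
    y = 0.2 * x + 0.5 * m + 0.3 * c1 + 0.2 * c2 + rng.normal(size=n)
    return pd.DataFrame({"x": x, "m": m, "y": y, "c1": c1, "c2": c2})
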