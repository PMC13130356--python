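import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import bioaging as ba

settings.register_profile(
    "ci", max_examples=50, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A modest default-condition cohort shared across read-only tests."""
    return ba.generate_cohort(ba.default_config(n_participants=4000, seed=7))


@pytest.fixture(scope="session")
def analytic_cohort(small_cohort):
    """Prepared analytic sample (exclusions + KDM + indices) and its model."""
    analytic, model, report = ba.build_analytic_cohort(small_cohort, ba.AnalysisConfig())
    return analytic, model, report


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
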