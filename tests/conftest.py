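import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import netoutcome as no

settings.register_profile(
    "suite", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")

# lasso paths emit harmless convergence chatter at extreme lambdas
warnings.filterwarnings("ignore", message=".*convergence.*")


@pytest.fixture(scope="session")
def scale():
    return no.hrsd17()


@pytest.fixture(scope="session")
def default_cohort(scale):
    """n=2000 cohort from the default generating model (three outcome edges)."""
    model = no.default_study_model(0)
    return no.sample_cohort(model, scale, no.SimulationConfig(n_patients=2000, seed=11))


@pytest.fixture(scope="session")
def default_network(default_cohort):
    return no.estimate_network(default_cohort, no.EstimationConfig(cv_seed=0))


@pytest.fixture(scope="session")
def indep_cohort(scale):
    """n=2000 pure-noise cohort (no edges, outcome independent of items)."""
    model = no.independence_model()
    return no.sample_cohort(model, scale, no.SimulationConfig(n_patients=2000, seed=901))


@pytest.fixture(scope="session")
def small_cohort(scale):
    """n=300 cohort for fast structural tests."""
    model = no.default_study_model(3)
    return no.sample_cohort(model, scale, no.SimulationConfig(n_patients=300, seed=77))
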