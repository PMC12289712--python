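import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from erythrosim import (ModelParameters, PopulationModel, TrialDesign,
                        derive_rates, steady_state, generate_trial)


@pytest.fixture(scope="session")
def typical():
    """Typical male parameter set."""
    return ModelParameters()


@pytest.fixture(scope="session")
def rates(typical):
    return derive_rates(typical)


@pytest.fixture(scope="session")
def baseline_state(typical):
    return steady_state(typical)


@pytest.fixture(scope="session")
def pop():
    return PopulationModel()


@pytest.fixture(scope="session")
def design():
    return TrialDesign()


@pytest.fixture(scope="session")
def trial_62(design, pop):
    """One full-size synthetic trial, shared across tests."""
    return generate_trial(design, pop, seed=101)
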