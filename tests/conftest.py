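import numpy as np
import pytest

from acekin import ParameterSet, State, model_variant


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    """Calibrated default parameter set."""
    return ParameterSet()


@pytest.fixture(scope="session")
def model4():
    return model_variant(4)


@pytest.fixture(scope="session")
def model1():
    return model_variant(1)


@pytest.fixture(scope="session")
def interior_state() -> State:
    """A generic strictly interior state for rate-law evaluations."""
    return State(GLC=15.0, ACE_env=0.1, X=0.5, ACCOA=0.2, ACP=0.05, ACE_cell=0.3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
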