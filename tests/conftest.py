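import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import myopia_cea as m

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def ref_params():
    """The shipped calibrated surrogate parameter set."""
    return m.load_reference_parameters()


@pytest.fixture(scope="session")
def guess_params():
    """A deterministic structurally-valid parameter set (not calibrated)."""
    return m.generate_initial_guess(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_chain_matrix(rng: np.random.Generator, age: int) -> m.TransitionMatrix:
    """Random forward-only progression matrix at one age."""
    return m.progression_matrix(age, *rng.uniform(0.0, 0.5, size=3))
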