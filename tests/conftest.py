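import numpy as np
import pytest

from mealmodel import reference_animal, simulate
from mealmodel.model_core import apply_steady_state


@pytest.fixture(scope="session")
def reference():
    """(params, z) of the built-in reference animal."""
    return reference_animal()


@pytest.fixture(scope="session")
def ref_params(reference):
    return reference[0]


@pytest.fixture(scope="session")
def ref_z(reference):
    return reference[1]


@pytest.fixture(scope="session")
def ref_traj(reference):
    """Reference 420-min trajectory at the paper step (dt=0.002)."""
    params, z = reference
    return simulate(params, z)


@pytest.fixture(scope="session")
def ss_params(ref_params):
    """Reference parameters with the basal steady state enforced exactly."""
    return apply_steady_state(ref_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
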