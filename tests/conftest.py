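import numpy as np
import pytest

from arthrosim import build_reference_patient, default_network, reference_state
from arthrosim.network import NetworkSpec


@pytest.fixture(scope="session")
def spec():
    return default_network()


@pytest.fixture(scope="session")
def reference(spec):
    return build_reference_patient(spec=spec)


@pytest.fixture(scope="session")
def ref_state():
    return reference_state()


@pytest.fixture(scope="session")
def ref_vector(ref_state):
    return ref_state.vector()


@pytest.fixture()
def bare_spec():
    """Network with every regulatory edge removed (decoupled model)."""
    s = NetworkSpec(
        secretion_edges=[("FLS", "IL6")],
        regulation_edges=[],
        differentiation_edges=[],
        essential_edges=[],
        cam=None,
    )
    s.validate()
    return s


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
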