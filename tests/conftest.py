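import numpy as np
import pytest

from qspect.phantom import PhantomSpec, generate_phantom_patient


@pytest.fixture(scope="session")
def phantom_patient():
    """One deterministic phantom patient shared across tests."""
    return generate_phantom_patient(PhantomSpec(), seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
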