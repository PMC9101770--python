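import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_unit_quats(rng, n):
    """Uniform random unit quaternions via normalized Gaussian 4-vectors."""
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


@pytest.fixture
def unit_quats():
    return random_unit_quats
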