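import numpy as np
import pytest

from ictalnet import (
    Connectome,
    ExcitabilityMap,
    ModelParams,
    generate_planted,
)


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture
def triangle():
    """Three nodes, all unit weights."""
    w = np.ones((3, 3)) - np.eye(3)
    return Connectome(w, normalized=True)


@pytest.fixture
def star5():
    """Five-node star with unit weights, node 0 in the center."""
    w = np.zeros((5, 5))
    w[0, 1:] = 1.0
    w[1:, 0] = 1.0
    return Connectome(w, normalized=True)


@pytest.fixture(scope="session")
def planted12():
    """Small planted scenario used by several dynamic tests."""
    return generate_planted(12, 2, seed=42)


@pytest.fixture(scope="session")
def planted12_ex(planted12):
    return ExcitabilityMap.from_ez(planted12.connectome.n, planted12.ez)


def random_connectome(n: int, seed: int, density: float = 0.5) -> Connectome:
    """Seeded random symmetric test matrix, max-normalized."""
    rng = np.random.default_rng(seed)
    w = rng.random((n, n)) * (rng.random((n, n)) < density)
    w = np.triu(w, k=1)
    w = w + w.T
    m = w.max()
    if m == 0:
        w[0, 1] = w[1, 0] = 1.0
        m = 1.0
    return Connectome(w / m, normalized=True)
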