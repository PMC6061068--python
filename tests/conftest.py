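import numpy as np
import pytest

from hiercme.characteristics import build_characteristics
from hiercme.hierarchy import decompose_hierarchic
from hiercme.network import InitialCondition, parse_reactions


@pytest.fixture(scope="session")
def catalysis():
    net = parse_reactions("X -> X + Y @ 20.0")
    return net, decompose_hierarchic(net)


@pytest.fixture(scope="session")
def catalysis_cs(catalysis):
    return build_characteristics(catalysis[1])


@pytest.fixture(scope="session")
def splitting():
    net = parse_reactions("X -> Y + Z @ 1.3")
    return net, decompose_hierarchic(net)


@pytest.fixture(scope="session")
def conversion_splitting():
    net = parse_reactions("X -> Y + Z @ 7.0\nY -> X @ 1.875")
    return net, decompose_hierarchic(net)


@pytest.fixture(scope="session")
def two_stage():
    net = parse_reactions(
        "0 -> X @ 1.2\nX -> 0 @ 1.2\nX -> X + Y @ 10.0\nY -> 0 @ 0.3"
    )
    return net, decompose_hierarchic(net)


@pytest.fixture(scope="session")
def bateman_chain():
    net = parse_reactions("X1 -> X2 + Y @ 3.1\nX2 -> X3 + Y @ 1.0")
    return net, decompose_hierarchic(net)


@pytest.fixture
def rng():
    return np.random.default_rng(20180120)


def poisson_ic(*means):
    return InitialCondition.poisson(list(means))


def random_polydisc_points(rng, n, count):
    """Random points inside the closed unit polydisc of C^n."""
    pts = rng.uniform(-1, 1, (count, n)) + 1j * rng.uniform(-1, 1, (count, n))
    norm = np.maximum(1.0, np.abs(pts).max(axis=1, keepdims=True))
    return pts / norm
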