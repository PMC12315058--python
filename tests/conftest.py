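import numpy as np
import pytest

from pahgeom import make_benzenoid, perceive_bonds, perceive_rings


@pytest.fixture(scope="session")
def benzene():
    return make_benzenoid(1)


@pytest.fixture(scope="session")
def naphthalene():
    return make_benzenoid(2)


@pytest.fixture(scope="session")
def acene5():
    return make_benzenoid(5)


@pytest.fixture(scope="session")
def pyrene():
    # 2x2 rhombus of cells: 4 rings, 16 carbons, 19 C-C bonds
    return make_benzenoid([(0, 0), (1, 0), (0, 1), (1, 1)])


@pytest.fixture(scope="session")
def triphenylene():
    # central ring fused to 3 mutually non-adjacent outer rings
    return make_benzenoid([(0, 0), (1, 0), (-1, 1), (0, -1)])


@pytest.fixture(scope="session")
def coronene():
    return make_benzenoid([(0, 0)] + list({(1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)}))


def random_rotation(rng):
    """Haar-ish random proper rotation via QR."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def perceived():
    """Helper returning (structure, graph, rings) for any structure."""

    def _build(structure):
        g = perceive_bonds(structure)
        return structure, g, perceive_rings(g)

    return _build
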