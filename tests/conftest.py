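import numpy as np
import pytest

from alignval.geometry import SymmetryGroup, sample_projection_grid
from alignval.imageops import project_directions
from alignval.synthetic import default_phantom_spec, make_phantom


@pytest.fixture(scope="session")
def c1():
    return SymmetryGroup("C1")


@pytest.fixture(scope="session")
def phantom32():
    return make_phantom(default_phantom_spec(32))


@pytest.fixture(scope="session")
def phantom48():
    return make_phantom(default_phantom_spec(48))


@pytest.fixture(scope="session")
def grid15(c1):
    return sample_projection_grid(15.0, c1)


@pytest.fixture(scope="session")
def refs32(phantom32, grid15):
    """Grid projections of the 32-box phantom at 15-degree sampling."""
    return project_directions(phantom32, grid15.eulers)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_matchset(rng, xi=7, index=0):
    """Random directions on the sphere with positive random weights."""
    from alignval.imageops import MatchSet

    d = rng.standard_normal((xi, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    w = rng.uniform(0.05, 1.0, xi)
    order = np.argsort(-w)
    return MatchSet(particle_index=index, directions=d[order], weights=w[order],
                    grid_indices=np.arange(xi))
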