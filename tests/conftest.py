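import numpy as np
import pytest

from dosepaint.core import ImageGrid, ROIMask, SUVVolume
from dosepaint.phantom import PhantomParams, generate_phantom


@pytest.fixture
def grid8():
    return ImageGrid(shape=(8, 8, 8), spacing=(2.0, 2.0, 2.0))


@pytest.fixture
def grid30():
    return ImageGrid(shape=(30, 30, 30), spacing=(2.0, 2.0, 2.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20140228)


@pytest.fixture
def small_phantom(grid30):
    """A modest phantom case reused across modules."""
    return generate_phantom(
        PhantomParams(grid=grid30, gtv_volume_ccm=30.0, correlation_rho=0.5, seed=7)
    )


@pytest.fixture
def default_phantom():
    """Cohort-average phantom on the default 48^3 grid."""
    return generate_phantom(PhantomParams(seed=1))


def random_case(rng, grid):
    """A random SUV volume + GTV on a small grid, for brute-force oracles."""
    values = rng.uniform(0.0, 10.0, size=grid.shape)
    gtv = rng.random(grid.shape) < 0.5
    if not gtv.any():
        gtv[tuple(d // 2 for d in grid.shape)] = True
    return (
        SUVVolume(grid=grid, values=values),
        ROIMask(grid=grid, member=gtv, label="GTV"),
    )
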