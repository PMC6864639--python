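import numpy as np
import pytest

from sfaeval import (
    ChromophoreLibrary,
    DEFAULT_GRID,
    Illuminant,
    SpectrumSet,
    WavelengthGrid,
)


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def small_grid():
    """Coarse 21-point lattice for cheap exact-algebra tests."""
    return WavelengthGrid(400.0, 600.0, 10.0)


@pytest.fixture(scope="session")
def equi(grid):
    return Illuminant.equi_energy(grid)


@pytest.fixture(scope="session")
def lib(grid):
    """Compiled-literature chromophore library on the default grid."""
    return ChromophoreLibrary.from_reference(grid=grid)


@pytest.fixture(scope="session")
def synthetic_lib(grid):
    """Synthetic triangular chromophore library (no real-world numbers)."""
    return ChromophoreLibrary.from_reference("chromophores_synthetic", grid=grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_set(grid):
    r = np.random.default_rng(7).uniform(0.05, 0.95, size=(12, grid.n_points))
    return SpectrumSet(grid, r, kind="test")
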