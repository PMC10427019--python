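import numpy as np
import pytest

from mlfit.grids import AtomSet, DensityGrid
from mlfit.spreading import SpreadParams, spread_density


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def grid_1d(x_min=-30.0, x_max=30.0, spacing=0.2) -> DensityGrid:
    """Degenerate 3D grid representing a 1D axis along x."""
    n = int(round((x_max - x_min) / spacing)) + 1
    return DensityGrid(np.zeros((n, 1, 1)), origin=(x_min, 0, 0), spacing=(spacing, 1, 1))


def gaussian_target_1d(centers, amplitudes=None, sigma=1.0, spacing=0.2,
                       x_min=-30.0, x_max=30.0, cutoff=4.0) -> DensityGrid:
    """1D target built by spreading point particles (the same forward model
    used for the model density)."""
    centers = np.atleast_1d(np.asarray(centers, float))
    pos = np.column_stack([centers, np.zeros_like(centers), np.zeros_like(centers)])
    amps = None if amplitudes is None else np.asarray(amplitudes, float)
    geom = grid_1d(x_min, x_max, spacing)
    return spread_density(AtomSet(pos, amps), geom, SpreadParams(sigma, cutoff))


@pytest.fixture
def random_target_3d(rng) -> DensityGrid:
    """Small random 3D map with some negative voxels (raw-map-like)."""
    return DensityGrid(rng.random((8, 8, 8)) - 0.1, origin=(0, 0, 0), spacing=(1, 1, 1))
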