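import numpy as np
import pytest

import roiselect as rs


def small_grid_spec(seed: int) -> rs.SyntheticSpec:
    """A 12x12-tile synthetic tissue small enough for exhaustive solver
    oracles (3x3 = 9 non-overlapping side-4 candidates)."""
    return rs.SyntheticSpec(
        image_size_px=12 * 32,
        tile_size_px=32,
        smoothness_px=64.0,
        dirichlet_conc=50.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def default_fixture():
    """The package's reference synthetic slide: 40x40 tiles of 256 px,
    K=7 contiguous clusters, seed 0."""
    spec = rs.SyntheticSpec(seed=0)
    grid, truth = rs.generate_tile_grid(spec, return_truth=True)
    return spec, grid, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
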