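"""Shared fixtures: small geometries kept cheap enough for property tests."""

import numpy as np
import pytest

from qmwi import ImagingGrid, PermittivityScene, circular_config


@pytest.fixture(scope="session")
def small_grid():
    return ImagingGrid(16, 16, 0.25)


@pytest.fixture(scope="session")
def small_config():
    return circular_config(4, 16, 1.67, [3e9])


@pytest.fixture()
def random_scene(small_grid):
    rng = np.random.default_rng(7)
    eps = 1.0 + 1.5 * rng.random((small_grid.ny, small_grid.nx))
    return PermittivityScene(small_grid, eps.astype(complex))
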