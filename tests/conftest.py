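"""Shared fixtures: small random cubes and synthetic scenes.

Everything is generated programmatically with fixed seeds; session scope is
used for the more expensive scenes so the suite stays fast.
"""

import numpy as np
import pytest

from samcover.datacube import Datacube, default_grid
from samcover.roi import ROI
from samcover.synth import ProductParams, SimConfig, generate_scene


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_cube(grid, rng):
    """A 16x16x32 cube of uniform random reflectance in (0.05, 0.95)."""
    data = rng.uniform(0.05, 0.95, (16, 16, len(grid)))
    return Datacube(data=data, grid=grid)


@pytest.fixture(scope="session")
def noisy_scene():
    """Default synthetic scene (spots + mottle, SNR 47, seed 7)."""
    return generate_scene(SimConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_full_opacity_scene():
    """Noiseless scene under a fully opaque product (analytic limit)."""
    return generate_scene(
        SimConfig(seed=7, snr=None, product=ProductParams(name="full", opacity=1.0))
    )


@pytest.fixture(scope="session")
def work_roi():
    return ROI("work", row0=16, col0=16, height_px=64, width_px=64)


@pytest.fixture(scope="session")
def ref_roi():
    return ROI("ref", row0=36, col0=36, height_px=24, width_px=24)
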