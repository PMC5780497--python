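"""Shared fixtures: a reference ellipse geometry and meshes at two scales."""

import numpy as np
import pytest

from flipdg.geometry import build_synthetic_geometry, triangulate
from flipdg.model import BleachSchedule


@pytest.fixture(scope="session")
def ellipse_geometry():
    """Concentric ellipse cell/nucleus with a cytoplasmic bleach spot.

    Cell semi-axes (6, 5) um, nucleus (2.5, 2) um, bleach disk of
    diameter 1.64 um centred 4 um right of the nucleus, in a 15x15 um
    field (origin lower-left).
    """
    return build_synthetic_geometry(
        ((7.5, 7.5), (6.0, 5.0)),
        ((7.5, 7.5), (2.5, 2.0)),
        (11.5, 7.5),
        bleach_diameter=1.64,
    )


@pytest.fixture(scope="session")
def coarse_mesh(ellipse_geometry):
    """~300-element interface-conforming mesh (fast unit tests)."""
    return triangulate(ellipse_geometry, 0.8)


@pytest.fixture(scope="session")
def medium_mesh(ellipse_geometry):
    """~400-element mesh, the calibration benchmark scale."""
    return triangulate(ellipse_geometry, 0.72)


@pytest.fixture(scope="session")
def schedule():
    """Protocol defaults: 0.8 s bleach + 1.8 s recovery, dt = 0.2 s."""
    return BleachSchedule()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def two_level_c0(coarse_mesh):
    """Initial intensity 0.4 in the cytoplasm, 0.9 in the nucleus."""
    region = np.repeat(coarse_mesh.element_region, 3)
    return np.where(region == 2, 0.9, 0.4).astype(float)
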