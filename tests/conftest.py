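"""Shared fixtures: reference gels, grids and synthetic scenes."""

import numpy as np
import pytest

from cytomech.elastics import GelSubstrate, GridSpec
from cytomech.synthio import DipoleSpec, simulate_traction_scene


@pytest.fixture(scope="session")
def gel_soft() -> GelSubstrate:
    return GelSubstrate(youngs_modulus=1e3, poisson_ratio=0.5)


@pytest.fixture(scope="session")
def grid64() -> GridSpec:
    return GridSpec(origin=(0.0, 0.0), spacing=1.0, shape=(64, 64))


@pytest.fixture(scope="session")
def dipole_center(grid64) -> tuple[float, float]:
    return (31.5, 31.5)


@pytest.fixture(scope="session")
def compact_dipole_scene(gel_soft, grid64, dipole_center):
    """Noiseless x-axis dipole compact enough for sub-1% plain inversion."""
    dip = DipoleSpec(
        center=dipole_center,
        axis_angle=0.0,
        force_magnitude=100.0,
        separation=10.0,
        patch_radius=2.0,
    )
    return simulate_traction_scene([dip], gel_soft, grid64, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def reference_dipole_scene(gel_soft, grid64, dipole_center):
    """The 100 pN / 20 µm dipole whose moment trace is -2000 pN·µm."""
    dip = DipoleSpec(
        center=dipole_center,
        axis_angle=0.0,
        force_magnitude=100.0,
        separation=20.0,
        patch_radius=2.0,
    )
    return simulate_traction_scene([dip], gel_soft, grid64, noise_sd=0.0, seed=0)


def relative_l2(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b) / np.linalg.norm(b))
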