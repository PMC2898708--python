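"""Shared fixtures: phantoms and sinograms reused across the suite."""

import numpy as np
import pytest

import sinosort as ss
from sinosort.phantoms import uniform_shuffled_angles

PHANTOM_SEED = 42  # the fixed-seed asymmetric fixture used throughout
GRID = 128
SAMPLES = 299


@pytest.fixture(scope="session")
def phantom():
    """Fixed-seed asymmetric 6-ellipse phantom, 128x128."""
    return ss.random_asymmetric_phantom(PHANTOM_SEED, GRID, 6)


@pytest.fixture(scope="session")
def disk_phantom():
    """Centered unit-intensity disk of radius 0.5."""
    return ss.make_ellipse_phantom([ss.Ellipse((0, 0), (0.5, 0.5))], GRID)


@pytest.fixture(scope="session")
def sino256(phantom):
    """256 noiseless projections at shuffled exactly-uniform angles."""
    angles = uniform_shuffled_angles(256, 1042)
    return ss.radon_project(phantom, angles, SAMPLES)


@pytest.fixture(scope="session")
def sino512(phantom):
    """512 noiseless projections at shuffled exactly-uniform angles."""
    angles = uniform_shuffled_angles(512, 2042)
    return ss.radon_project(phantom, angles, SAMPLES)


@pytest.fixture(scope="session")
def fourfold_phantom():
    """Exactly 4-fold rotationally symmetric phantom (failure-mode fixture)."""
    base = ss.make_ellipse_phantom(
        [ss.Ellipse((0.45, 0.0), (0.18, 0.1), 0.3, 0.8),
         ss.Ellipse((0.0, 0.0), (0.2, 0.2), 0.0, 0.5)], GRID)
    return (base + np.rot90(base) + np.rot90(base, 2) + np.rot90(base, 3)) / 4.0


def circular_separations(angles):
    """Pairwise shortest-arc separations, for oracle constructions."""
    angles = np.asarray(angles)
    diff = angles[:, None] - angles[None, :]
    return np.abs((diff + np.pi) % (2 * np.pi) - np.pi)
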