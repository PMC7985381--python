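"""Shared fixtures: small phantoms and projection stacks sized for fast tests."""

import numpy as np
import pytest

from optmorph.simulate import (PhantomSpec, default_angles, forward_project,
                               generate_phantom)


@pytest.fixture(scope="session")
def small_spec():
    """25 well-separated spherical-ish cells in a 64^3 tube section."""
    return PhantomSpec(
        volume_shape_voxels=(64, 64, 64),
        voxel_pitch_um=5.0,
        tube_inner_diameter_um=280.0,
        n_cells=25,
        semi_axis_range_um=(8.0, 14.0),
        rng_seed=3,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    vol, truth = generate_phantom(small_spec)
    return vol, truth


@pytest.fixture(scope="session")
def angles400():
    return default_angles(400)


@pytest.fixture(scope="session")
def small_stack(small_phantom, angles400):
    vol, _ = small_phantom
    return forward_project(vol, angles400, 0.0, 5.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
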