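"""Shared fixtures: small phantoms reused across the suite."""

import numpy as np
import pytest

from fontanflow import (FluidProperties, GridSpec, make_poiseuille_tube,
                        make_solid_body_rotation, make_tcpc_phantom,
                        make_uniform_flow)


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec.centered((21, 21, 21), (1.0, 1.0, 1.0), n_frames=4,
                             frame_duration=40.0)


@pytest.fixture(scope="session")
def poiseuille_1mm(fluid):
    """R = 8 mm, L = 60 mm, Vbar = 0.3 m/s tube at 1 mm isotropic."""
    grid = GridSpec.centered((25, 25, 69), (1.0, 1.0, 1.0), n_frames=1)
    return make_poiseuille_tube(grid, radius=8.0, length=60.0,
                                mean_velocity=0.3, fluid=fluid)


@pytest.fixture(scope="session")
def rotation_series():
    grid = GridSpec.centered((41, 41, 17), (1.0, 1.0, 1.0), n_frames=1)
    return make_solid_body_rotation(grid, omega=5.0)


@pytest.fixture(scope="session")
def uniform_series(small_grid):
    return make_uniform_flow(small_grid, (0.0, 0.0, 0.2))


@pytest.fixture(scope="session")
def tcpc_default():
    """Symmetric-split TCPC phantom on the study-like acquisition grid."""
    return make_tcpc_phantom(split_ivc_to_lpa=0.5)


@pytest.fixture(scope="session")
def tcpc_80():
    return make_tcpc_phantom(split_ivc_to_lpa=0.8)
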