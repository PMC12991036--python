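"""Shared fixtures.

The default-resolution femur sweep is expensive (minutes), so it is built
once per session and shared by the acceptance tests; unit tests use small
structured meshes or a coarse femur.
"""

import dataclasses

import numpy as np
import pytest

from femursweep import (
    FemurParams,
    RunConfig,
    assign_materials,
    compute_frame,
    generate_femur,
    make_tube_mesh,
    run_sweep,
)


@pytest.fixture(scope="session")
def default_params():
    return FemurParams(seed=1)


@pytest.fixture(scope="session")
def coarse_params(default_params):
    return dataclasses.replace(default_params, grid_spacing=8.0)


@pytest.fixture(scope="session")
def coarse_femur(coarse_params):
    return generate_femur(coarse_params)


@pytest.fixture(scope="session")
def coarse_frame(coarse_femur):
    frame, registered = compute_frame(coarse_femur)
    return frame, registered


@pytest.fixture(scope="session")
def coarse_materials(coarse_femur):
    return assign_materials(coarse_femur, None, None, "two_phase")


@pytest.fixture(scope="session")
def two_phase_tube():
    """Hollow tube with an exact cortical-trabecular interface ring at
    r = 12.5 mm (trabecular 10-12.5, cortical 12.5-20)."""
    return make_tube_mesh(
        r_inner=10.0, r_outer=20.0, length=100.0,
        n_r=4, n_theta=24, n_z=20, interface_radius=12.5,
    )


@pytest.fixture(scope="session")
def default_sweep(default_params):
    """Full sweep on the default synthetic femur; shared by the acceptance
    tests (balancing, loss patterns, monotonicity, loss-correlation)."""
    cfg = RunConfig(femur=default_params)
    return run_sweep(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
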