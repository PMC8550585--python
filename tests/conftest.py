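"""Shared fixtures: small deterministic scenes used across the suite."""

import numpy as np
import pytest

from softcut import RunConfig, VolumeModel, build_scene, build_sim_tables
from softcut.model import generate_torus_volume


@pytest.fixture(scope="session")
def small_torus():
    """Coarse solid torus: a few hundred nodes/elements."""
    return generate_torus_volume(1.0, 0.3, 0.15)


@pytest.fixture(scope="session")
def small_tables(small_torus):
    return build_sim_tables(small_torus, None)


@pytest.fixture()
def cube_model():
    """Single integration element surrounded by its 8 cube-corner nodes."""
    h = 0.1
    corners = (
        np.array(
            [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
            dtype=float,
        )
        * h
    )
    return VolumeModel(
        node_positions=corners,
        element_centers=np.array([[0.5 * h, 0.5 * h, 0.5 * h]]),
        element_volumes=np.array([h**3]),
        grid_spacing=h,
    )


@pytest.fixture(scope="session")
def tiny():
    """A <= 30-node model with full tables, for dense-oracle comparisons.

    A 3x3x3 grid block (27 nodes, 8 cubic elements) — small enough for
    explicit 3n x 3n assembly and dense eigen/linear solves.
    """
    from softcut import MaterialParams

    h = 0.1
    nodes = np.array(
        [[i, j, k] for i in range(3) for j in range(3) for k in range(3)],
        dtype=float,
    ) * h
    centers = np.array(
        [[i + 0.5, j + 0.5, k + 0.5] for i in range(2) for j in range(2)
         for k in range(2)],
        dtype=float,
    ) * h
    model = VolumeModel(
        node_positions=nodes,
        element_centers=centers,
        element_volumes=np.full(8, h**3),
        grid_spacing=h,
    )
    assert model.n_nodes <= 30
    tables = build_sim_tables(model, None)
    return model, tables, MaterialParams()


@pytest.fixture(scope="session")
def demo_config():
    """A small but complete cutting-demo configuration."""
    return RunConfig(
        grid_spacing=0.15,
        surface_n_u=20,
        surface_n_v=10,
        n_frames=30,
        cut_start_frame=4,
        cut_n_frames=16,
        batch_size=16,
    )


@pytest.fixture()
def demo_scene(demo_config):
    # function-scoped: simulations mutate the scene's tables
    return build_scene(demo_config)
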