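import numpy as np
import pytest

from hexcomb import (
    EulerGrid,
    build_scene,
    build_unit_cell,
    hex_cluster_layout,
    hex_prism_mesh,
    sphere_mesh,
)


@pytest.fixture(scope="session")
def unit_cell():
    return build_unit_cell(1.0, 2.0, 0.12)


@pytest.fixture(scope="session")
def sphere():
    return sphere_mesh(2.0, 0.1)


@pytest.fixture(scope="session")
def unit_sphere():
    return sphere_mesh(1.0, 0.08)


@pytest.fixture(scope="session")
def hex_prism():
    return hex_prism_mesh(1.0, 2.0, 0.08)


@pytest.fixture()
def small_grid():
    return EulerGrid(40, 40, 40, 0.25)


@pytest.fixture(scope="session")
def cluster7():
    """7-cell hexagonal cluster in a 40^3 h=0.25 domain."""
    grid = EulerGrid(40, 40, 40, 0.25)
    scene = build_scene(
        7, 1.0, 2.0, 0.1, 0.125,
        layout=hex_cluster_layout(),
        domain=grid.extent,
        clearance=0.5,
    )
    return scene


def center_cell_index(scene):
    centers = scene.centers
    return int(np.argmin(np.linalg.norm(centers - centers.mean(axis=0), axis=1)))
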