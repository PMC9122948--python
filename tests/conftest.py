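import numpy as np
import pytest

from colonycomp import DomainGeometry, build_disk_mesh, FounderConfiguration


@pytest.fixture(scope="session")
def small_geometry():
    return DomainGeometry(R=30.0, R0=10.0, target_element_area=0.72)


@pytest.fixture(scope="session")
def small_mesh(small_geometry):
    """Cheap mesh for unit tests (~2k nodes, 211 inoculum nodes)."""
    return build_disk_mesh(small_geometry)


@pytest.fixture(scope="session")
def default_mesh():
    """The production geometry (R=72, R0=14, element area 0.36)."""
    return build_disk_mesh(DomainGeometry())


@pytest.fixture(scope="session")
def coarse_mesh():
    """Ensemble geometry: same domain, four-fold coarser elements."""
    return build_disk_mesh(DomainGeometry(target_element_area=1.44))


def config_from_points(points, strains, seed=None):
    return FounderConfiguration(np.asarray(points, float), np.asarray(strains, int), seed=seed)


@pytest.fixture
def config_factory():
    return config_from_points
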