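import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ecm_material():
    from cellscale.microgen import Material

    return Material(c1=1.6892, c2=0.0, K=83.3333)


@pytest.fixture(scope="session")
def voxel_sphere_coords():
    """(ne, 8, 3) element coordinates of a unit sphere voxelized at 40
    elements across the diameter."""
    from cellscale.mesh import structured_hex_grid

    r = 40
    mesh = structured_hex_grid((r, r, r), (2.0, 2.0, 2.0), origin=(-1.0, -1.0, -1.0))
    cents = mesh.element_centroids()
    inside = (cents**2).sum(axis=1) <= 1.0
    return mesh.element_coords()[inside]


def warped_hex(rng, scale=0.25):
    """A randomly warped but untangled hexahedron."""
    from cellscale.hexkernel import NATURAL_CORNERS, jacobian

    while True:
        coords = NATURAL_CORNERS + scale * rng.standard_normal((8, 3))
        try:
            for p in NATURAL_CORNERS * 0.99:
                jacobian(coords, p)
        except ValueError:
            continue
        return coords
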