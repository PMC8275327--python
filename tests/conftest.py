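import numpy as np
import pytest
import trimesh

from astroskin.pipeline import PipelineConfig, mesh_morphology
from astroskin.synth import SynthAstroParams, generate_astrocyte


@pytest.fixture(scope="session")
def small_params():
    """Scaled-down astrocyte for fast unit tests."""
    return SynthAstroParams(
        seed=7, n_arbors=3, max_branch_order=2, n_endfeet=1,
        trunk_section_length=5.0,
    )


@pytest.fixture(scope="session")
def small_astro(small_params):
    return generate_astrocyte(small_params)


@pytest.fixture(scope="session")
def tiny_params():
    """No endfeet: the coarse min-radius resolution makes meshing near-instant."""
    return SynthAstroParams(
        seed=3, n_arbors=2, max_branch_order=2, n_endfeet=0,
        trunk_section_length=4.0,
    )


@pytest.fixture(scope="session")
def default_astro():
    """Full-size synthetic astrocyte at generator defaults."""
    return generate_astrocyte(SynthAstroParams(seed=42))


@pytest.fixture(scope="session")
def default_mesh(default_astro):
    """Polygonized surface of the default astrocyte (single partition)."""
    mesh, info = mesh_morphology(default_astro, PipelineConfig())
    return mesh, info


@pytest.fixture()
def icosphere():
    return trimesh.creation.icosphere(subdivisions=3, radius=5.0)


@pytest.fixture()
def dense_sphere():
    return trimesh.creation.icosphere(subdivisions=5, radius=5.0)


def grid_patch(n=3, extent=10.0, thickness=2.0):
    """Flat square endfoot-like patch fixture."""
    from astroskin.morphology import EndfootPatch

    xs = np.linspace(0, extent, n)
    verts = np.array([[x, y, 0.0] for y in xs for x in xs])
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            tris += [[a, a + 1, a + n], [a + 1, a + n + 1, a + n]]
    return EndfootPatch(
        vertices=verts,
        thickness=np.full(n * n, float(thickness)),
        triangles=np.array(tris),
    )
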