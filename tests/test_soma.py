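import numpy as np
import pytest
import trimesh

from astroskin import meshops
from astroskin.metaballs import polygonize, skin_segment
from astroskin.morphology import Sample
from astroskin.soma import (
    SoftBodyParams,
    simulate_soma_surface,
    skin_soma_hybrid,
    skin_soma_marching,
    uniform_remesh,
)


@pytest.fixture()
def soma():
    return Sample(id=1, position=[0, 0, 0], radius=5.0, parent_id=None)


@pytest.fixture()
def roots():
    return [
        Sample(id=2, position=[10, 0, 0], radius=1.0, parent_id=1),
        Sample(id=3, position=[0, 9, 0], radius=1.2, parent_id=1),
        Sample(id=4, position=[0, 0, -8], radius=0.9, parent_id=1),
    ]


class TestMarching:
    def test_no_arbors_single_ball(self, soma):
        mo = skin_soma_marching(soma, [])
        assert len(mo) == 1

    def test_counting_oracle(self, soma):
        root = Sample(id=2, position=[10, 0, 0], radius=1.0, parent_id=1)
        mo = skin_soma_marching(soma, [root], 1.0)
        assert len(mo) == len(skin_segment(soma, root, 1.0)) + 1

    def test_arbor_order_invariant(self, soma, roots):
        a = skin_soma_marching(soma, roots)
        b = skin_soma_marching(soma, roots[::-1])
        key = lambda mo: sorted(map(tuple, np.round(mo.centers, 12)))
        assert key(a) == key(b)

    def test_single_partition_with_arbors(self, soma, roots):
        mo = skin_soma_marching(soma, roots, 1.0)
        mo.resolution = 0.5
        mesh = polygonize(mo)
        assert len(meshops.split_partitions(mesh)) == 1


class TestSoftBody:
    def test_no_arbors_stays_spherical(self, soma):
        mesh = simulate_soma_surface(soma, [], seed=0)
        assert mesh.volume == pytest.approx(4 / 3 * np.pi * soma.radius**3, rel=0.02)

    def test_euler_characteristic_preserved(self, soma, roots):
        mesh = simulate_soma_surface(soma, roots, seed=0)
        assert mesh.euler_number == 2
        assert mesh.is_watertight

    def test_energy_non_increasing_after_freeze(self, soma, roots):
        _, hist = simulate_soma_surface(soma, roots, seed=0, return_history=True)
        tail = hist["spring_energy"][hist["n_pull_steps"] :]
        assert np.all(np.diff(tail) <= 1e-9)

    def test_deterministic_given_seed(self, soma, roots):
        a = simulate_soma_surface(soma, roots, seed=3)
        b = simulate_soma_surface(soma, roots, seed=3)
        assert np.array_equal(a.vertices, b.vertices)


class TestUniformRemesh:
    def test_area_budget_vertex_count(self):
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        spacing = 0.2
        cloud = uniform_remesh(sphere, spacing, seed=0)
        budget = sphere.area / (np.sqrt(3) / 2 * spacing**2)
        assert 0.7 * budget <= len(cloud.vertices) <= 1.3 * budget

    def test_spacing_cv(self):
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        cloud = uniform_remesh(sphere, 0.2, seed=0)
        assert cloud.spacing_cv() <= 0.35

    def test_points_on_surface(self):
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        cloud = uniform_remesh(sphere, 0.2, seed=0)
        r = np.linalg.norm(cloud.vertices, axis=1)
        assert np.all(np.abs(r - 1.0) <= 0.2)

    def test_spacing_too_large_raises(self):
        sphere = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        with pytest.raises(ValueError, match="diameter"):
            uniform_remesh(sphere, 50.0)


@pytest.fixture(scope="module")
def sphere_cloud():
    sphere = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
    return sphere, uniform_remesh(sphere, 0.4, seed=1)


class TestHybrid:
    def test_two_partitions_before_pruning(self, sphere_cloud):
        _, cloud = sphere_cloud
        mesh = polygonize(skin_soma_hybrid(cloud, base_resolution=0.6))
        assert len(meshops.split_partitions(mesh)) == 2

    def test_exterior_volume_matches_input(self, sphere_cloud):
        sphere, cloud = sphere_cloud
        mesh = polygonize(skin_soma_hybrid(cloud, base_resolution=0.6))
        outer = meshops.remove_interior_partition(mesh)
        assert abs(outer.volume) == pytest.approx(sphere.volume, rel=0.10)

    def test_exterior_encloses_cloud_vertices(self, sphere_cloud):
        from astroskin._geom import ray_parity_inside

        _, cloud = sphere_cloud
        mesh = polygonize(skin_soma_hybrid(cloud, base_resolution=0.6))
        outer = meshops.remove_interior_partition(mesh)
        tris = np.asarray(outer.triangles)
        for v in cloud.vertices[::150]:
            assert ray_parity_inside(v, tris)

    def test_exterior_not_smaller_than_interior(self, sphere_cloud):
        _, cloud = sphere_cloud
        mesh = polygonize(skin_soma_hybrid(cloud, base_resolution=0.6))
        a, b = meshops.split_partitions(mesh)
        assert abs(a.volume) >= abs(b.volume)

    def test_coverage_condition_enforced(self, sphere_cloud):
        _, cloud = sphere_cloud
        with pytest.raises(ValueError, match="coverage"):
            skin_soma_hybrid(cloud, base_resolution=0.1)


def test_softbody_params_validation():
    with pytest.raises(ValueError):
        SoftBodyParams(damping=1.5)
    with pytest.raises(ValueError):
        SoftBodyParams(stiffness=-1)
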