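import numpy as np
import pytest
import trimesh

from astroskin import meshops
from astroskin.synth import generate_defect_mesh


def two_spheres(gap=20.0):
    a = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
    b = trimesh.creation.icosphere(subdivisions=2, radius=2.0)
    b.apply_translation([gap, 0, 0])
    return trimesh.util.concatenate([a, b])


class TestPartitions:
    def test_two_disjoint_spheres(self):
        parts = meshops.split_partitions(two_spheres())
        assert len(parts) == 2
        # ordered by descending volume
        assert abs(parts[0].volume) > abs(parts[1].volume)

    def test_single_sphere(self, icosphere):
        assert len(meshops.split_partitions(icosphere)) == 1

    def test_membership_matches_union_find_oracle(self):
        mesh = two_spheres()
        F = np.asarray(mesh.faces)
        parent = list(range(len(mesh.vertices)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for f in F:
            for u, v in ((f[0], f[1]), (f[1], f[2])):
                ru, rv = find(int(u)), find(int(v))
                if ru != rv:
                    parent[ru] = rv
        labels = {find(int(f[0])) for f in F}
        assert len(labels) == len(meshops.split_partitions(mesh))

    def test_remove_interior_concentric(self):
        outer = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
        inner = trimesh.creation.icosphere(subdivisions=2, radius=2.0)
        mesh = trimesh.util.concatenate([outer, inner])
        kept = meshops.remove_interior_partition(mesh)
        assert abs(kept.volume) == pytest.approx(outer.volume, rel=1e-6)

    def test_remove_interior_single_partition_errors(self, icosphere):
        with pytest.raises(ValueError, match="2 partitions"):
            meshops.remove_interior_partition(icosphere)

    def test_remove_interior_not_nested_errors(self):
        with pytest.raises(ValueError, match="nested"):
            meshops.remove_interior_partition(two_spheres(gap=30.0))


class TestNonManifold:
    def test_closed_icosphere_clean(self, icosphere):
        assert meshops.count_non_manifold(icosphere) == (0, 0)

    def test_three_triangles_sharing_edge(self):
        mesh = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1]],
            faces=[[0, 1, 2], [0, 1, 3], [0, 1, 4]],
            process=False,
        )
        edges, _ = meshops.count_non_manifold(mesh)
        assert edges == 1

    def test_pinched_vertex(self):
        # two fans meeting only at vertex 0
        mesh = trimesh.Trimesh(
            vertices=[
                [0, 0, 0],
                [1, 0, 0], [1, 1, 0],
                [-1, 0, 0], [-1, -1, 0],
            ],
            faces=[[0, 1, 2], [0, 3, 4]],
            process=False,
        )
        _, verts = meshops.count_non_manifold(mesh)
        assert verts >= 1


class TestSelfIntersections:
    def test_icosphere_zero(self, icosphere):
        assert meshops.detect_self_intersections(icosphere) == 0

    def test_interpenetrating_pair(self):
        mesh = trimesh.Trimesh(
            vertices=[
                [0, 0, 0], [2, 0, 0], [0, 2, 0],
                [0.5, 0.5, -1], [1.5, 0.5, 1], [0.5, 1.5, 1],
            ],
            faces=[[0, 1, 2], [3, 4, 5]],
            process=False,
        )
        assert meshops.detect_self_intersections(mesh) == 1

    def test_random_soup_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(11)
        V = rng.uniform(0, 10, (200, 3, 3))
        soup = trimesh.Trimesh(
            vertices=V.reshape(-1, 3),
            faces=np.arange(600).reshape(-1, 3),
            process=False,
        )
        pruned = meshops.detect_self_intersections(soup)
        brute = meshops.detect_self_intersections(soup, brute_force=True)
        assert pruned == brute
        assert brute > 0


class TestDecimate:
    def test_ratio_volume_extent(self, dense_sphere):
        out = meshops.decimate(dense_sphere, 0.1)
        assert len(out.faces) <= 0.1 * len(dense_sphere.faces) + 1
        assert out.volume == pytest.approx(dense_sphere.volume, rel=0.05)
        ext_in = dense_sphere.bounds[1] - dense_sphere.bounds[0]
        ext_out = out.bounds[1] - out.bounds[0]
        assert np.abs(ext_out - ext_in).max() <= 0.01 * np.linalg.norm(ext_in)

    def test_preserves_genus_zero(self, dense_sphere):
        out = meshops.decimate(dense_sphere, 0.1)
        assert out.euler_number == 2
        assert out.is_watertight

    def test_near_identity_ratio(self, icosphere):
        out = meshops.decimate(icosphere, 0.999)
        assert len(out.faces) >= 0.95 * len(icosphere.faces)

    def test_invalid_ratio(self, icosphere):
        with pytest.raises(ValueError):
            meshops.decimate(icosphere, 1.5)


class TestRepair:
    def test_hole_refilled(self, icosphere):
        broken = generate_defect_mesh("hole", seed=2)
        fixed = meshops.repair_watertight(broken)
        report = meshops.mesh_metrics(fixed)
        assert report.watertight
        assert abs(fixed.volume) == pytest.approx(icosphere.volume, rel=0.01)

    def test_idempotent_on_watertight(self, icosphere):
        once = meshops.repair_watertight(icosphere)
        twice = meshops.repair_watertight(once)
        assert len(twice.faces) == len(once.faces)
        assert twice.volume == pytest.approx(once.volume)

    def test_inverted_orientation_fixed(self):
        fixed = meshops.repair_watertight(generate_defect_mesh("inverted", seed=0))
        assert fixed.volume > 0

    @pytest.mark.parametrize("kind", ["hole", "fin", "inverted", "two_shells"])
    def test_all_defects_end_watertight(self, kind):
        fixed = meshops.repair_watertight(generate_defect_mesh(kind, seed=1))
        assert meshops.mesh_metrics(fixed).watertight


class TestMetrics:
    def test_unit_cube(self):
        cube = trimesh.creation.box(extents=(1, 1, 1))
        report = meshops.mesh_metrics(cube)
        assert report.surface_area == pytest.approx(6.0)
        assert report.volume == pytest.approx(1.0)
        assert report.watertight

    def test_icosphere_volume_closed_form(self):
        fine = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        report = meshops.mesh_metrics(fine, check_self_intersections=False)
        assert report.volume == pytest.approx(4 * np.pi / 3, rel=0.01)

    def test_area_rigid_invariant(self, icosphere):
        moved = icosphere.copy()
        T = trimesh.transformations.rotation_matrix(0.7, [1, 2, 3], [4, 5, 6])
        moved.apply_transform(T)
        assert moved.area == pytest.approx(icosphere.area, rel=1e-9)


class TestHausdorff:
    def test_identical_zero(self, icosphere):
        assert meshops.hausdorff_rms(icosphere, icosphere, 5000, seed=1) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_concentric_spheres_closed_form(self):
        a = trimesh.creation.icosphere(subdivisions=5, radius=1.0)
        b = trimesh.creation.icosphere(subdivisions=5, radius=1.01)
        h = meshops.hausdorff_rms(a, b, samples=20000, seed=7)
        diag = np.linalg.norm(a.bounds[1] - a.bounds[0])
        assert h == pytest.approx(0.01 / diag, rel=0.05)

    def test_deterministic_given_seed(self, icosphere, dense_sphere):
        h1 = meshops.hausdorff_rms(icosphere, dense_sphere, 2000, seed=3)
        h2 = meshops.hausdorff_rms(icosphere, dense_sphere, 2000, seed=3)
        assert h1 == h2
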