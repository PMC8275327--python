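import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from astroskin import meshops
from astroskin.metaballs import (
    ISO_LEVEL,
    SURFACE_FRACTION,
    EmptyMeshError,
    MetaObject,
    blend,
    field_value,
    influence_radius,
    kernel_value,
    polygonize,
    skin_arbor,
    skin_segment,
)
from astroskin.morphology import Sample


class TestKernel:
    def test_maximum_at_center(self):
        assert kernel_value(0.0, 3.0) == 1.0

    def test_compact_support(self):
        assert kernel_value(3.0, 3.0) == 0.0
        assert kernel_value(10.0, 3.0) == 0.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            kernel_value(-0.1, 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(d=st.floats(0.0, 0.999), r=st.floats(0.5, 20.0))
    def test_strictly_decreasing_inside_support(self, d, r):
        a = kernel_value(d * r, r)
        b = kernel_value(min((d + 1e-3) * r, r), r)
        assert b <= a

    def test_surface_fraction_root_finding_oracle(self):
        # the iso-0.5 crossing of the kernel, found independently
        root = brentq(lambda d: kernel_value(d, 1.0) - ISO_LEVEL, 0.0, 1.0)
        assert root == pytest.approx(SURFACE_FRACTION, abs=1e-12)
        assert root == pytest.approx(0.4542, abs=1e-4)


class TestField:
    def test_empty_meta_object_zero(self):
        mo = MetaObject.empty()
        pts = np.random.default_rng(0).uniform(-5, 5, (20, 3))
        assert np.all(field_value(mo, pts) == 0)

    def test_coincident_balls_additive(self):
        mo1 = MetaObject(centers=[[0, 0, 0]], radii=[2.0])
        mo2 = MetaObject(centers=[[0, 0, 0], [0, 0, 0]], radii=[2.0, 2.0])
        pts = np.random.default_rng(1).uniform(-3, 3, (50, 3))
        assert np.allclose(field_value(mo2, pts), 2 * field_value(mo1, pts))

    def test_indexed_equals_brute_force(self):
        rng = np.random.default_rng(3)
        mo = MetaObject(
            centers=rng.uniform(0, 20, (1000, 3)),
            radii=rng.uniform(0.5, 3.0, 1000),
        )
        pts = rng.uniform(-2, 22, (200, 3))
        fast = field_value(mo, pts)
        brute = field_value(mo, pts, brute_force=True)
        assert np.allclose(fast, brute, atol=1e-9, rtol=0)


class TestSkinSegment:
    def sample(self, pos, r, sid=1):
        return Sample(id=sid, position=pos, radius=r, parent_id=None)

    def test_zero_length(self):
        a = self.sample([1, 2, 3], 2.0)
        mo = skin_segment(a, self.sample([1, 2, 3], 2.0, 2), 1.0)
        assert len(mo) == 1
        assert np.allclose(mo.centers[0], [1, 2, 3])

    def test_counting_oracle(self):
        # length 10, radii (1,1), step 1 -> ceil(10/1)+1 = 11 balls, 1 µm apart
        a = self.sample([0, 0, 0], 1.0)
        b = self.sample([10, 0, 0], 1.0, 2)
        mo = skin_segment(a, b, 1.0)
        assert len(mo) == 11
        gaps = np.linalg.norm(np.diff(mo.centers, axis=0), axis=1)
        assert np.allclose(gaps, 1.0)
        assert np.allclose(mo.radii * SURFACE_FRACTION, 1.0)

    def test_midpoint_radius_interpolation(self):
        a = self.sample([0, 0, 0], 1.0)
        b = self.sample([4, 0, 0], 3.0, 2)
        mo = skin_segment(a, b, 1.0)
        mid = len(mo) // 2
        assert mo.radii[mid] * SURFACE_FRACTION == pytest.approx(2.0)

    def test_spacing_bound(self):
        a = self.sample([0, 0, 0], 0.7)
        b = self.sample([5.3, 0, 0], 2.0, 2)
        mo = skin_segment(a, b, 1.0)
        gaps = np.linalg.norm(np.diff(mo.centers, axis=0), axis=1)
        assert np.all(gaps <= 0.7 + 1e-12)


class TestSkinArbor:
    def test_single_section_equals_segment(self, small_astro):
        from astroskin.morphology import Arbor, Section

        a = Sample(id=1, position=[0, 0, 0], radius=1.0, parent_id=None)
        b = Sample(id=2, position=[5, 0, 0], radius=1.0, parent_id=1)
        arbor = Arbor(root_section=Section(samples=[a, b]))
        mo = skin_arbor(arbor, 1.0)
        ref = skin_segment(a, b, 1.0)
        assert np.array_equal(mo.centers, ref.centers)

    def test_bifurcation_counting_oracle(self):
        from astroskin.morphology import Arbor, Section

        a = Sample(id=1, position=[0, 0, 0], radius=1.0, parent_id=None)
        b = Sample(id=2, position=[5, 0, 0], radius=1.0, parent_id=1)
        c = Sample(id=3, position=[8, 3, 0], radius=0.8, parent_id=2)
        d = Sample(id=4, position=[8, -3, 0], radius=0.8, parent_id=2)
        root = Section(samples=[a, b])
        s1 = Section(samples=[b, c], parent_section=root)
        s2 = Section(samples=[b, d], parent_section=root)
        root.child_sections = [s1, s2]
        mo = skin_arbor(Arbor(root_section=root), 1.0)
        expected = sum(
            len(skin_segment(x, y, 1.0))
            for x, y in [(a, b), (b, c), (b, d)]
        )
        assert len(mo) == expected
        assert mo.resolution == pytest.approx(0.8)

    def test_resolution_is_min_radius(self, small_astro):
        arbor = small_astro.arbors[0]
        mo = skin_arbor(arbor, 1.0)
        radii = [s.radius for sec in arbor.sections() for s in sec.samples]
        assert mo.resolution == pytest.approx(min(radii))


class TestBlend:
    def test_identity(self):
        mo = MetaObject(centers=[[0, 0, 0]], radii=[1.0], resolution=0.5)
        out = blend([mo])
        assert np.array_equal(out.centers, mo.centers)
        assert out.resolution == 0.5

    def test_field_additivity(self):
        rng = np.random.default_rng(5)
        parts = [
            MetaObject(centers=rng.uniform(0, 5, (10, 3)), radii=rng.uniform(0.5, 2, 10))
            for _ in range(3)
        ]
        merged = blend(parts)
        pts = rng.uniform(-1, 6, (100, 3))
        total = sum(field_value(p, pts) for p in parts)
        assert np.allclose(field_value(merged, pts), total)

    def test_min_resolution(self):
        a = MetaObject(centers=[[0, 0, 0]], radii=[1.0], resolution=0.7)
        b = MetaObject(centers=[[1, 0, 0]], radii=[1.0], resolution=0.3)
        assert blend([a, b]).resolution == pytest.approx(0.3)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            blend([])


class TestPolygonize:
    def single_ball(self, surface_r=4.542, spacing=0.5):
        return MetaObject(
            centers=[[0, 0, 0]],
            radii=[influence_radius(surface_r)],
            resolution=spacing,
        )

    def test_sphere_topology(self):
        mesh = polygonize(self.single_ball())
        assert mesh.is_watertight
        assert mesh.euler_number == 2
        assert len(meshops.split_partitions(mesh)) == 1

    def test_volume_closed_form_and_convergence(self):
        surface_r = 4.542
        expected = 4 / 3 * np.pi * surface_r**3
        v_coarse = polygonize(self.single_ball(surface_r, 0.5)).volume
        assert v_coarse == pytest.approx(expected, rel=0.05)
        v_fine = polygonize(self.single_ball(surface_r, 0.25)).volume
        assert abs(v_fine - v_coarse) / v_coarse < 0.02

    def test_disjoint_vs_touching_components(self):
        r = influence_radius(1.0)
        far = MetaObject(
            centers=[[0, 0, 0], [3 * r, 0, 0]], radii=[r, r], resolution=0.25
        )
        assert len(meshops.split_partitions(polygonize(far))) == 2
        near = MetaObject(
            centers=[[0, 0, 0], [1.2, 0, 0]], radii=[r, r], resolution=0.25
        )
        assert len(meshops.split_partitions(polygonize(near))) == 1

    def test_volume_monotone_in_balls(self):
        r = influence_radius(1.0)
        one = MetaObject(centers=[[0, 0, 0]], radii=[r], resolution=0.2)
        two = MetaObject(
            centers=[[0, 0, 0], [1.0, 0, 0]], radii=[r, r], resolution=0.2
        )
        assert polygonize(two).volume >= polygonize(one).volume

    def test_too_coarse_raises(self):
        mo = MetaObject(centers=[[0, 0, 0]], radii=[0.2], resolution=10.0)
        with pytest.raises(EmptyMeshError, match="resolution"):
            polygonize(mo)

    def test_manifold_guarantee(self, default_mesh):
        mesh, _ = default_mesh
        assert meshops.count_non_manifold(mesh) == (0, 0)
        assert meshops.boundary_edge_count(mesh) == 0
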