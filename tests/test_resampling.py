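import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from astroskin.morphology import Sample, Section
from astroskin.resampling import (
    ResamplingPolicy,
    adaptive_resample_section,
    morphometry_report,
    resample_morphology,
)


def straight_section(n=101, spacing=0.1, radius=1.0):
    samples = [
        Sample(
            id=i + 1,
            position=[i * spacing, 0, 0],
            radius=radius,
            parent_id=None if i == 0 else i,
        )
        for i in range(n)
    ]
    return Section(samples=samples)


def greedy_oracle(positions, radii, factor):
    """Independent greedy scan: indices kept by the spacing rule."""
    kept = [0]
    for i in range(1, len(positions) - 1):
        last = kept[-1]
        if np.linalg.norm(positions[i] - positions[last]) >= factor * radii[last]:
            kept.append(i)
    kept.append(len(positions) - 1)
    return kept


class TestAdaptiveResample:
    def test_dense_straight_section_matches_greedy_oracle(self):
        sec = straight_section(n=101, spacing=0.1, radius=1.0)
        out = adaptive_resample_section(sec, ResamplingPolicy(1.0))
        pos = sec.polyline()
        rad = sec.radii()
        expect = greedy_oracle(pos, rad, 1.0)
        assert [s.id for s in out.samples] == [sec.samples[i].id for i in expect]
        # 0.1 µm spacing, radius 1, factor 1 -> kept every 10th + endpoints
        assert len(out.samples) == 11

    def test_two_sample_section_unchanged(self):
        sec = straight_section(n=2, spacing=0.01)
        out = adaptive_resample_section(sec, ResamplingPolicy(1.0))
        assert [s.id for s in out.samples] == [s.id for s in sec.samples]

    def test_sparse_section_noop(self):
        sec = straight_section(n=5, spacing=10.0, radius=1.0)
        out = adaptive_resample_section(sec, ResamplingPolicy(1.0))
        assert len(out.samples) == 5

    def test_endpoints_verbatim(self):
        sec = straight_section()
        out = adaptive_resample_section(sec, ResamplingPolicy(2.5))
        assert out.samples[0] is sec.samples[0]
        assert out.samples[-1] is sec.samples[-1]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        f1=st.floats(0.1, 5.0),
        f2=st.floats(0.1, 5.0),
    )
    def test_monotonic_in_spacing_factor(self, f1, f2):
        lo, hi = sorted((f1, f2))
        sec = straight_section(n=80, spacing=0.13, radius=0.7)
        n_lo = len(adaptive_resample_section(sec, ResamplingPolicy(lo)).samples)
        n_hi = len(adaptive_resample_section(sec, ResamplingPolicy(hi)).samples)
        assert n_hi <= n_lo

    def test_hausdorff_shape_bound(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(0.05 * rng.normal(size=(200, 3)), axis=0)
        samples = [
            Sample(id=i + 1, position=p, radius=0.5, parent_id=None if i == 0 else i)
            for i, p in enumerate(pts)
        ]
        sec = Section(samples=samples)
        factor = 1.0
        out = adaptive_resample_section(sec, ResamplingPolicy(factor))
        kept = out.polyline()
        # every original point within factor*max_radius of the kept polyline
        dmax = 0.0
        for p in pts:
            seg = kept[1:] - kept[:-1]
            t = np.clip(
                np.einsum("ij,ij->i", p - kept[:-1], seg)
                / np.maximum(np.einsum("ij,ij->i", seg, seg), 1e-30),
                0,
                1,
            )
            proj = kept[:-1] + t[:, None] * seg
            dmax = max(dmax, np.linalg.norm(proj - p, axis=1).min())
        assert dmax <= factor * max(s.radius for s in sec.samples)


class TestResampleMorphology:
    def test_counts(self, small_astro):
        out = resample_morphology(small_astro, ResamplingPolicy(1.0))
        assert out.n_samples() < small_astro.n_samples()
        assert out.n_sections() == small_astro.n_sections()

    def test_idempotent(self, small_astro):
        p = ResamplingPolicy(1.0)
        once = resample_morphology(small_astro, p)
        twice = resample_morphology(once, p)
        assert [s.id for s in twice.samples()] == [s.id for s in once.samples()]

    def test_endfeet_untouched(self, small_astro):
        out = resample_morphology(small_astro, ResamplingPolicy(1.0))
        assert len(out.endfeet) == len(small_astro.endfeet)
        assert out.endfeet[0] is small_astro.endfeet[0]


class TestMorphometry:
    def test_identical_inputs_zero_deltas(self, small_astro):
        cmp = morphometry_report(small_astro, small_astro)
        assert cmp.relative_cable_change == 0
        assert cmp.sample_count_delta == 0
        assert cmp.section_count_delta == 0

    def test_cable_length_change_small(self, small_astro):
        out = resample_morphology(small_astro, ResamplingPolicy(1.0))
        cmp = morphometry_report(small_astro, out)
        assert cmp.section_count_delta == 0
        assert cmp.relative_cable_change < 0.02

    def test_cable_length_matches_polyline_arclength_oracle(self, small_astro):
        cmp = morphometry_report(small_astro, small_astro)
        brute = 0.0
        for arbor in small_astro.arbors:
            for sec in arbor.sections():
                pts = sec.polyline()
                brute += float(
                    np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
                )
        assert cmp.cable_length_before == pytest.approx(brute)

    def test_topology_mismatch_raises(self, small_astro):
        from astroskin.synth import SynthAstroParams, generate_astrocyte

        other = generate_astrocyte(
            SynthAstroParams(seed=1, n_arbors=2, max_branch_order=2)
        )
        with pytest.raises(ValueError):
            morphometry_report(small_astro, other)
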