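"""Adaptive skeleton resampling.

Synthesized astrocyte processes are heavily oversampled (sample spacing far
below the local radius), which makes per-segment metaball marching
needlessly expensive.  Resampling keeps a sample only once it is at least
``spacing_factor`` local radii away from the previously kept sample, with
section endpoints always preserved, so the retained polyline is a subset of
the original and no detail below the polygonization resolution is lost.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from astroskin.morphology import Arbor, AstrocyteMorphology, Section


@dataclass
class ResamplingPolicy:
    """Greedy arc-walk policy.

    spacing_factor: minimum spacing between kept samples as a multiple of
    the radius of the previously kept sample (unitless, default 1.0).
    Endpoints are always preserved.
    """

    spacing_factor: float = 1.0

    def __post_init__(self):
        if not self.spacing_factor > 0:
            raise ValueError("spacing_factor must be > 0")


def adaptive_resample_section(sec: Section, policy: ResamplingPolicy) -> Section:
    """Return a resampled copy of a section (links not rewired).

    Kept samples are a subset of the originals: first and last are retained
    verbatim, and an interior sample is kept iff its Euclidean distance from
    the last kept sample is >= spacing_factor * radius(last kept sample).
    """
    if len(sec.samples) < 2:
        raise ValueError("section must have >= 2 samples")
    kept = [sec.samples[0]]
    for s in sec.samples[1:-1]:
        last = kept[-1]
        if np.linalg.norm(s.position - last.position) >= (
            policy.spacing_factor * last.radius
        ):
            kept.append(s)
    kept.append(sec.samples[-1])
    return Section(samples=kept)


def resample_morphology(
    m: AstrocyteMorphology, policy: ResamplingPolicy
) -> AstrocyteMorphology:
    """Resample every section; section topology and endfeet are untouched."""

    def rebuild(sec: Section, parent_new: Section | None) -> Section:
        new = adaptive_resample_section(sec, policy)
        if parent_new is not None:
            # keep the shared branch-sample object shared
            new.samples[0] = parent_new.samples[-1]
            new.parent_section = parent_new
        for child in sec.child_sections:
            new.child_sections.append(rebuild(child, new))
        return new

    arbors = [Arbor(root_section=rebuild(a.root_section, None)) for a in m.arbors]
    return AstrocyteMorphology(
        soma=copy.deepcopy(m.soma), arbors=arbors, endfeet=list(m.endfeet)
    )


@dataclass
class ArborMorphometry:
    cable_length: float
    n_sections: int
    n_samples: int
    max_branch_order: int


@dataclass
class MorphometryComparison:
    before: list[ArborMorphometry]
    after: list[ArborMorphometry]

    @property
    def cable_length_before(self) -> float:
        return sum(a.cable_length for a in self.before)

    @property
    def cable_length_after(self) -> float:
        return sum(a.cable_length for a in self.after)

    @property
    def relative_cable_change(self) -> float:
        lb = self.cable_length_before
        if lb == 0:
            return 0.0
        return abs(self.cable_length_after - lb) / lb

    @property
    def sample_count_delta(self) -> int:
        return sum(a.n_samples for a in self.after) - sum(
            a.n_samples for a in self.before
        )

    @property
    def section_count_delta(self) -> int:
        return sum(a.n_sections for a in self.after) - sum(
            a.n_sections for a in self.before
        )


def _arbor_morphometry(a: Arbor) -> ArborMorphometry:
    return ArborMorphometry(
        cable_length=a.cable_length(),
        n_sections=a.n_sections(),
        n_samples=sum(1 for _ in a.samples()),
        max_branch_order=a.max_branch_order(),
    )


def morphometry_report(
    before: AstrocyteMorphology, after: AstrocyteMorphology
) -> MorphometryComparison:
    """Per-arbor cable length / counts before vs after resampling.

    Raises ValueError when the two morphologies do not share section
    topology (arbor count or per-arbor section count mismatch).
    """
    if len(before.arbors) != len(after.arbors):
        raise ValueError("arbor count mismatch between morphologies")
    b = [_arbor_morphometry(a) for a in before.arbors]
    a = [_arbor_morphometry(x) for x in after.arbors]
    for i, (mb, ma) in enumerate(zip(b, a)):
        if mb.n_sections != ma.n_sections:
            raise ValueError(
                f"arbor {i}: section count changed "
                f"({mb.n_sections} -> {ma.n_sections}); topology mismatch"
            )
    return MorphometryComparison(before=b, after=a)
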