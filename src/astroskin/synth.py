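"""Deterministic synthetic astrocyte-like test data.

The generator emulates the geometric/topological shape class of a cortical
astrocyte — a single-sample soma, several tapering binary-branching arbors
densely oversampled along their polylines, and a couple of open endfeet
patches wrapped part-way around a virtual vessel cylinder near arbor tips —
without attempting statistical fidelity to biological morphometrics.  Every
stochastic choice flows through one seeded generator, so outputs are
byte-identical across runs with the same parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from astroskin.morphology import (
    Arbor,
    AstrocyteMorphology,
    EndfootPatch,
    Sample,
    Section,
    StructureType,
)


@dataclass
class SynthAstroParams:
    """Generator knobs (distances in µm).

    ``taper`` is the child/parent radius ratio applied per branch order, so
    the smallest skeleton radius is ``soma_radius * taper**max_branch_order``.
    ``oversample_spacing`` is the dense sample spacing along sections, far
    below the local radius, to exercise adaptive resampling.
    """

    seed: int = 0
    n_arbors: int = 6
    max_branch_order: int = 4
    soma_radius: float = 6.0
    taper: float = 0.8
    oversample_spacing: float = 0.05
    n_endfeet: int = 2
    vessel_radius: float = 4.0
    trunk_section_length: float = 7.0
    section_length_decay: float = 0.8
    turn_rate: float = 0.05  # rad/µm of smooth meander along sections

    def __post_init__(self):
        if not 0 < self.taper < 1:
            raise ValueError("taper must be in (0, 1)")
        for name in (
            "n_arbors",
            "max_branch_order",
            "soma_radius",
            "oversample_spacing",
            "vessel_radius",
            "trunk_section_length",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def _perp(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        r = rng.normal(size=3)
        p = r - np.dot(r, v) * v
        n = np.linalg.norm(p)
        if n > 1e-8:
            return p / n


class _IdAllocator:
    def __init__(self, start: int = 1):
        self.next_id = start

    def take(self) -> int:
        i = self.next_id
        self.next_id += 1
        return i


def generate_astrocyte(params: SynthAstroParams) -> AstrocyteMorphology:
    """Build a deterministic astrocyte-like morphology.

    Soma at the origin; ``n_arbors`` random-walk binary trees whose radii
    taper from ``soma_radius * taper`` (trunk start) down to
    ``soma_radius * taper**max_branch_order`` at the terminals; endfeet
    patches wrapped part-way around a virtual vessel near the tips of the
    first ``n_endfeet`` arbors.
    """
    rng = np.random.default_rng(params.seed)
    ids = _IdAllocator()
    soma = Sample(
        id=ids.take(),
        position=np.zeros(3),
        radius=params.soma_radius,
        parent_id=None,
        structure_type=StructureType.SOMA,
    )

    trunk_dirs = _fibonacci_sphere(params.n_arbors)
    # deterministic per-arbor jitter
    trunk_dirs = trunk_dirs + 0.1 * rng.normal(size=trunk_dirs.shape)
    trunk_dirs /= np.linalg.norm(trunk_dirs, axis=1, keepdims=True)

    def radius_at(order: int) -> float:
        return params.soma_radius * params.taper**order

    arbors: list[Arbor] = []
    tip_info: list[tuple[np.ndarray, np.ndarray]] = []  # (tip pos, direction)

    for ai in range(params.n_arbors):
        structure = (
            StructureType.PERIVASCULAR_PROCESS
            if ai % 2 == 0
            else StructureType.PERISYNAPTIC_PROCESS
        )

        def build(
            start: np.ndarray,
            direction: np.ndarray,
            order: int,
            first_sample: Sample | None,
            parent_id: int,
        ) -> Section:
            length = params.trunk_section_length * (
                params.section_length_decay ** (order - 1)
            )
            r0, r1 = radius_at(order - 1) * 0.999, radius_at(order)
            n_steps = max(2, int(np.ceil(length / params.oversample_spacing)))
            samples: list[Sample] = []
            if first_sample is not None:
                samples.append(first_sample)
                pid = first_sample.id
            else:
                entry = Sample(
                    id=ids.take(),
                    position=start.copy(),
                    radius=r0,
                    parent_id=parent_id,
                    structure_type=structure,
                )
                samples.append(entry)
                pid = entry.id
            pos = start.copy()
            d = direction / np.linalg.norm(direction)
            # smooth meander: persistent turning axis, so the dense polyline
            # is smooth below the radius scale (like synthesized processes)
            turn_axis = _perp(d, rng)
            turn = params.turn_rate * rng.uniform(0.5, 1.5)
            step_len = length / n_steps
            for k in range(1, n_steps + 1):
                d = _rodrigues(d, turn_axis, turn * step_len)
                d /= np.linalg.norm(d)
                pos = pos + step_len * d
                t = k / n_steps
                s = Sample(
                    id=ids.take(),
                    position=pos.copy(),
                    radius=r0 + t * (r1 - r0),
                    parent_id=pid,
                    structure_type=structure,
                )
                pid = s.id
                samples.append(s)
            sec = Section(samples=samples)
            if order < params.max_branch_order:
                axis = _perp(d, rng)
                for sign in (1.0, -1.0):
                    angle = sign * np.deg2rad(rng.uniform(20.0, 35.0))
                    child_dir = _rodrigues(d, axis, angle)
                    child = build(
                        samples[-1].position, child_dir, order + 1,
                        samples[-1], samples[-1].id,
                    )
                    child.parent_section = sec
                    sec.child_sections.append(child)
            else:
                tip_info.append((samples[-1].position.copy(), d.copy()))
            return sec

        start = trunk_dirs[ai] * params.soma_radius * 0.95
        root = build(start, trunk_dirs[ai], 1, None, soma.id)
        arbors.append(Arbor(root_section=root))

    endfeet = [
        _make_endfoot(tip_info[j * (len(tip_info) // max(params.n_endfeet, 1))],
                      params, rng)
        for j in range(params.n_endfeet)
    ]
    return AstrocyteMorphology(soma=soma, arbors=arbors, endfeet=endfeet)


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * np.dot(axis, v) * (1 - np.cos(angle))
    )


def _make_endfoot(
    tip: tuple[np.ndarray, np.ndarray],
    params: SynthAstroParams,
    rng: np.random.Generator,
) -> EndfootPatch:
    """Open patch on a virtual vessel cylinder touching an arbor tip.

    The vessel axis runs perpendicular to the arriving process; the patch
    spans ~100 degrees of arc and ~6 µm along the axis, triangulated as a
    7x7 grid, with per-vertex thickness drawn uniformly from [0.5, 1.5] µm.
    """
    tip_pos, tip_dir = tip
    axis = _perp(tip_dir, rng)
    vessel_center = tip_pos + tip_dir * params.vessel_radius
    # local frame: u points back toward the tip, v = axis
    u = -tip_dir
    w = np.cross(axis, u)
    w /= np.linalg.norm(w)

    n_u, n_v = 7, 7
    arc = np.deg2rad(100.0)
    span = 6.0
    thetas = np.linspace(-arc / 2, arc / 2, n_v)
    zs = np.linspace(-span / 2, span / 2, n_u)
    verts = []
    for z in zs:
        for th in thetas:
            p = (
                vessel_center
                + params.vessel_radius * (np.cos(th) * u + np.sin(th) * w)
                + z * axis
            )
            verts.append(p)
    verts = np.array(verts)
    tris = []
    for i in range(n_u - 1):
        for j in range(n_v - 1):
            a = i * n_v + j
            b = a + 1
            c = a + n_v
            d = c + 1
            tris.append([a, b, c])
            tris.append([b, d, c])
    thickness = rng.uniform(0.5, 1.5, size=len(verts))
    patch = EndfootPatch(
        vertices=verts, thickness=thickness, triangles=np.array(tris)
    )
    patch.validate()
    return patch


def generate_defect_mesh(kind: str, seed: int = 0) -> trimesh.Trimesh:
    """Icosphere with a named defect injected, for repair/QC tests.

    kind: 'hole' (one face removed), 'fin' (extra face on an existing
    edge), 'inverted' (all windings flipped), 'two_shells' (nested
    concentric spheres).
    """
    rng = np.random.default_rng(seed)
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
    V = np.asarray(sphere.vertices)
    F = np.asarray(sphere.faces)
    if kind == "hole":
        drop = int(rng.integers(len(F)))
        keep = np.ones(len(F), dtype=bool)
        keep[drop] = False
        return trimesh.Trimesh(vertices=V, faces=F[keep], process=False)
    if kind == "fin":
        a, b, c = F[int(rng.integers(len(F)))]
        apex = V[[a, b]].mean(axis=0) + np.array([0.0, 0.0, 2.0])
        V2 = np.vstack([V, apex[None, :]])
        F2 = np.vstack([F, [[a, b, len(V2) - 1]]])
        return trimesh.Trimesh(vertices=V2, faces=F2, process=False)
    if kind == "inverted":
        return trimesh.Trimesh(vertices=V, faces=F[:, ::-1], process=False)
    if kind == "two_shells":
        inner = trimesh.creation.icosphere(subdivisions=2, radius=2.0)
        V2 = np.vstack([V, np.asarray(inner.vertices)])
        F2 = np.vstack([F, np.asarray(inner.faces) + len(V)])
        return trimesh.Trimesh(vertices=V2, faces=F2, process=False)
    raise ValueError(f"unknown defect kind {kind!r}")
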