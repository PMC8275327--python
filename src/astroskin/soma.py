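"""Somatic surface reconstruction.

Two schemes, mirroring the two ways a one-sample soma (origin + mean
radius) can be turned into a meta-object:

* **origin-to-arbor metaball marching** — one meta-soma ball at the somatic
  sample plus a marched somatic segment toward each arbor root, with radii
  tapering linearly from the soma radius to the root radius.  Fast, and
  guarantees a single partition after blending with the arbors.

* **hybrid** — a mass-spring (Hooke) relaxation of an icosphere pulled
  toward the arbor roots gives a physically plausible somatic surface; the
  surface is remeshed into a uniform point cloud, and one metaball per
  cloud vertex is displaced inward along the vertex normal by its own
  effective surface radius.  Polygonizing the resulting meta-patches alone
  yields exactly two partitions (an exterior shell reproducing the input
  surface, plus an interior one) — the interior is pruned downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from astroskin._geom import MeshProximity
from astroskin.metaballs import MetaObject, blend, influence_radius, skin_segment
from astroskin.morphology import Sample


@dataclass
class SoftBodyParams:
    """Mass-spring relaxation parameters.

    stiffness: spring-force scale (unitless); steps: relaxation steps;
    damping: step-size multiplier in (0, 1) for the overdamped update;
    pull_fraction: how far toward each arbor root the surface is drawn,
    as a fraction of the center-to-root distance beyond the soma radius.
    """

    stiffness: float = 0.1
    steps: int = 100
    damping: float = 0.5
    pull_fraction: float = 0.4

    def __post_init__(self):
        if not (self.stiffness > 0 and self.steps > 0):
            raise ValueError("stiffness and steps must be positive")
        if not 0 < self.damping < 1:
            raise ValueError("damping must be in (0, 1)")
        if not 0 < self.pull_fraction <= 1:
            raise ValueError("pull_fraction must be in (0, 1]")


@dataclass
class UniformSurfaceCloud:
    """Approximately uniformly spaced points on a surface with outward
    normals; ``target_spacing`` in µm."""

    vertices: np.ndarray
    normals: np.ndarray
    target_spacing: float

    def nn_spacing(self) -> np.ndarray:
        d, _ = cKDTree(self.vertices).query(self.vertices, k=2)
        return d[:, 1]

    def spacing_cv(self) -> float:
        nn = self.nn_spacing()
        return float(nn.std() / nn.mean())


def skin_soma_marching(
    soma: Sample, arbor_roots: list[Sample], step_factor: float = 1.0
) -> MetaObject:
    """Meta-soma ball + one marched somatic segment per arbor root."""
    parts = [
        MetaObject(
            centers=soma.position[None, :],
            radii=np.array([influence_radius(soma.radius)]),
            resolution=soma.radius,
        )
    ]
    for root in arbor_roots:
        parts.append(skin_segment(soma, root, step_factor))
    return blend(parts)


def simulate_soma_surface(
    soma: Sample,
    arbor_roots: list[Sample],
    params: SoftBodyParams | None = None,
    seed: int = 0,
    subdivisions: int = 3,
    return_history: bool = False,
):
    """Relax an icosphere into a soma profile drawn toward the arbor roots.

    Overdamped Hooke dynamics: each step moves vertices along the net
    spring force (rest lengths = initial icosphere edge lengths) plus,
    during the first 60% of the steps, a pull toward each arbor-root
    direction.  Connectivity is never edited, so the result stays a
    closed genus-0 surface.  Deterministic given ``seed``.
    """
    params = params or SoftBodyParams()
    rng = np.random.default_rng(seed)
    base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=soma.radius)
    center = soma.position.astype(float)
    V = np.asarray(base.vertices) + center
    F = np.asarray(base.faces)
    edges = np.unique(np.sort(np.vstack([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]]), axis=1), axis=0)
    rest = np.linalg.norm(V[edges[:, 0]] - V[edges[:, 1]], axis=1)

    pulls = []
    for root in arbor_roots:
        to_root = root.position - center
        dist = float(np.linalg.norm(to_root))
        if dist == 0:
            continue
        u = to_root / dist
        target_r = soma.radius + params.pull_fraction * max(dist - soma.radius, 0.0)
        half_angle = float(np.clip(2.0 * np.arctan2(root.radius, dist), 0.25, 1.0))
        pulls.append((u, target_r, half_angle))

    n_pull_steps = int(round(0.6 * params.steps))
    step_size = params.damping * 0.5
    energies = []
    max_disp = []
    for step in range(params.steps):
        diff = V[edges[:, 1]] - V[edges[:, 0]]
        length = np.linalg.norm(diff, axis=1)
        safe = np.where(length == 0, 1.0, length)
        f_edge = params.stiffness * (length - rest)[:, None] * (diff / safe[:, None])
        force = np.zeros_like(V)
        np.add.at(force, edges[:, 0], f_edge)
        np.add.at(force, edges[:, 1], -f_edge)
        if step < n_pull_steps:
            radial = V - center
            rnorm = np.linalg.norm(radial, axis=1)
            rdir = radial / np.where(rnorm == 0, 1.0, rnorm)[:, None]
            for u, target_r, half_angle in pulls:
                w = np.clip(
                    (rdir @ u - np.cos(half_angle)) / (1.0 - np.cos(half_angle)),
                    0.0,
                    1.0,
                )
                force += (0.2 * w * (target_r - rnorm))[:, None] * rdir
        disp = step_size * force
        V = V + disp
        max_disp.append(float(np.abs(disp).max()))
        stretch = np.linalg.norm(V[edges[:, 1]] - V[edges[:, 0]], axis=1) - rest
        energies.append(float(0.5 * params.stiffness * np.sum(stretch**2)))

    tail = max(2, params.steps // 10)
    if len(max_disp) > tail and max_disp[-1] > max_disp[-tail]:
        warnings.warn(
            "soma soft-body relaxation did not converge: per-step "
            "displacement still growing over the final steps",
            RuntimeWarning,
        )
    mesh = trimesh.Trimesh(vertices=V, faces=F, process=False)
    if return_history:
        return mesh, {
            "spring_energy": np.array(energies),
            "max_displacement": np.array(max_disp),
            "n_pull_steps": n_pull_steps,
        }
    return mesh


def uniform_remesh(
    mesh: trimesh.Trimesh, target_spacing: float, seed: int = 0, iterations: int = 50
) -> UniformSurfaceCloud:
    """Particle-style uniform resampling of a closed surface.

    Area-weighted random sampling at the hexagonal-packing budget
    (area / (sqrt(3)/2 * spacing^2)) followed by on-surface repulsion
    relaxation: each iteration pushes points apart along the tangent plane
    and re-projects them onto the surface.
    """
    extent = float(np.linalg.norm(mesh.bounds[1] - mesh.bounds[0]))
    if target_spacing > extent:
        raise ValueError(
            f"target_spacing {target_spacing} exceeds surface diameter {extent:.3g}"
        )
    n = max(16, int(round(mesh.area / (np.sqrt(3.0) / 2.0 * target_spacing**2))))
    pts, fidx = trimesh.sample.sample_surface(mesh, n, seed=seed)
    pts = np.asarray(pts, dtype=float)
    prox = MeshProximity(mesh)
    face_normals = np.asarray(mesh.face_normals)
    r_c = 1.8 * target_spacing
    for _ in range(iterations):
        tree = cKDTree(pts)
        pairs = tree.query_pairs(r=r_c, output_type="ndarray")
        force = np.zeros_like(pts)
        if len(pairs):
            diff = pts[pairs[:, 0]] - pts[pairs[:, 1]]
            d = np.linalg.norm(diff, axis=1)
            safe = np.where(d == 0, 1.0, d)
            mag = (1.0 - d / r_c) ** 2
            push = (mag / safe)[:, None] * diff
            np.add.at(force, pairs[:, 0], push)
            np.add.at(force, pairs[:, 1], -push)
        pts = pts + 0.3 * target_spacing * force
        cp, _ = prox.closest(pts)
        pts = cp
    # normals from the supporting faces
    cp, _ = prox.closest(pts)
    # nearest face: re-query candidate triangles via closest points
    _, fi = cKDTree(np.asarray(mesh.triangles_center)).query(cp)
    normals = face_normals[fi]
    return UniformSurfaceCloud(
        vertices=pts, normals=normals, target_spacing=target_spacing
    )


def skin_soma_hybrid(
    cloud: UniformSurfaceCloud,
    base_resolution: float | None = None,
    ball_radius_factor: float = 1.25,
) -> MetaObject:
    """One inward-displaced metaball per cloud vertex.

    Every ball gets surface-effective radius ``r_eff = ball_radius_factor *
    max nearest-neighbor spacing`` and its center displaced by ``-r_eff``
    along the vertex normal, so the exterior partition of the polygonized
    field passes through the input surface to first order.  Raises when the
    cloud spacing violates the coverage condition (max spacing must stay
    below the polygonization resolution).
    """
    from astroskin.metaballs import ISO_LEVEL, field_value

    nn = cloud.nn_spacing()
    max_nn = float(nn.max())
    if base_resolution is not None and max_nn >= base_resolution:
        raise ValueError(
            f"cloud spacing {max_nn:.3g} µm violates the coverage "
            f"condition: it must be smaller than the polygonization "
            f"resolution {base_resolution:.3g} µm"
        )
    r_eff = ball_radius_factor * max_nn
    radii = np.full(len(cloud.vertices), influence_radius(r_eff))

    # The displacement step is the blended iso-offset, not the single-ball
    # surface radius: with overlapping neighbors the summed field crosses
    # the iso-level well outside each ball's own surface.  Find, per
    # vertex, where the undisplaced field crosses the iso-level along the
    # outward normal (vectorized bisection), and displace by that much so
    # the exterior isosurface passes through the input surface to first
    # order.
    mo0 = MetaObject(centers=cloud.vertices, radii=radii, resolution=r_eff)
    lo = np.zeros(len(cloud.vertices))
    hi = np.full(len(cloud.vertices), influence_radius(r_eff) * 1.5)
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        f = field_value(mo0, cloud.vertices + mid[:, None] * cloud.normals)
        outside = f < ISO_LEVEL
        hi[outside] = mid[outside]
        lo[~outside] = mid[~outside]
    step = 0.5 * (lo + hi)
    centers = cloud.vertices - step[:, None] * cloud.normals
    resolution = base_resolution if base_resolution is not None else r_eff
    return MetaObject(centers=centers, radii=radii, resolution=min(resolution, r_eff))
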