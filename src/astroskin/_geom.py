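"""Vectorized geometry kernels: point-to-triangle closest points,
triangle-triangle intersection, and ray-parity point containment.

These back the mesh QC and Hausdorff machinery.  Candidate pruning uses
scipy KD-trees; every pruned query is exactly equivalent to the brute-force
pairwise computation it replaces.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def closest_point_on_triangles(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Closest point on triangle ``tris[i]`` to ``points[i]`` (paired query).

    points: (N, 3); tris: (N, 3, 3).  Returns (N, 3).
    Ericson's region classification, fully vectorized.
    """
    p = np.asarray(points, dtype=float)
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1 - d3
    v = np.where(denom != 0, d1 / np.where(denom == 0, 1.0, denom), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2 - d6
    w = np.where(denom != 0, d2 / np.where(denom == 0, 1.0, denom), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    w = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1.0, denom), 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


class MeshProximity:
    """Point-to-surface queries against a fixed triangle mesh.

    A KD-tree over triangle centroids plus one over vertices provides
    candidate triangles; exact point-triangle distances are then evaluated
    only on the candidates.  Results equal the brute-force minimum over all
    triangles.
    """

    def __init__(self, mesh):
        self.mesh = mesh
        self.triangles = np.asarray(mesh.triangles)
        self.centroids = self.triangles.mean(axis=1)
        # circumscribing bound: max centroid-to-vertex distance per triangle
        self._tri_reach = np.linalg.norm(
            self.triangles - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self._rmax = float(self._tri_reach.max()) if len(self.triangles) else 0.0
        self._ctree = cKDTree(self.centroids)
        self._vtree = cKDTree(np.asarray(mesh.vertices))

    def distance(self, points: np.ndarray, chunk: int = 20000) -> np.ndarray:
        """Unsigned distance from each point to the surface."""
        return self.closest(points, chunk=chunk)[1]

    def closest(self, points: np.ndarray, chunk: int = 20000):
        """Closest surface points and distances: returns (points, dists)."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        out_p = np.empty_like(pts)
        out_d = np.empty(len(pts))
        for s in range(0, len(pts), chunk):
            block = pts[s : s + chunk]
            cp, d = self._closest_block(block)
            out_p[s : s + chunk] = cp
            out_d[s : s + chunk] = d
        return out_p, out_d

    def _closest_block(self, pts: np.ndarray):
        # upper bound from nearest vertex, then gather all triangles whose
        # centroid could beat it
        d_up, _ = self._vtree.query(pts)
        radii = d_up + self._rmax + 1e-12
        cand = self._ctree.query_ball_point(pts, r=radii)
        counts = np.fromiter((len(c) for c in cand), dtype=np.int64, count=len(pts))
        # a vertex of the mesh is itself on some triangle, so counts >= 1
        pt_idx = np.repeat(np.arange(len(pts)), counts)
        tri_idx = np.concatenate([np.asarray(c, dtype=np.int64) for c in cand])
        cp = closest_point_on_triangles(pts[pt_idx], self.triangles[tri_idx])
        d = np.linalg.norm(cp - pts[pt_idx], axis=1)
        # segmented argmin: pt_idx is non-decreasing, so after a stable sort
        # by (pt_idx, d) each group's first element is its minimum
        starts = np.zeros(len(pts), dtype=np.int64)
        np.cumsum(counts[:-1], out=starts[1:])
        order = np.lexsort((d, pt_idx))
        best_j = order[starts]
        return cp[best_j], d[best_j]


# ---------------------------------------------------------------------------
# Triangle-triangle intersection (Moller 1997), vectorized over pairs


def _project_coplanar(tri: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Project (N,3,3) triangles to the 2D plane dropping the largest
    normal component."""
    drop = np.argmax(np.abs(n), axis=1)
    keep = np.array([[1, 2], [0, 2], [0, 1]])[drop]
    idx = np.arange(len(tri))[:, None, None]
    return tri[idx, np.arange(3)[None, :, None], keep[:, None, :]]


def _segments_intersect_2d(p1, p2, q1, q2) -> np.ndarray:
    def orient(a, b, c):
        return (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (
            b[:, 1] - a[:, 1]
        ) * (c[:, 0] - a[:, 0])

    d1 = orient(q1, q2, p1)
    d2 = orient(q1, q2, p2)
    d3 = orient(p1, p2, q1)
    d4 = orient(p1, p2, q2)
    return ((d1 * d2) < 0) & ((d3 * d4) < 0)


def _point_in_tri_2d(p, tri) -> np.ndarray:
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]

    def cross(o, u, v):
        return (u[:, 0] - o[:, 0]) * (v[:, 1] - o[:, 1]) - (
            u[:, 1] - o[:, 1]
        ) * (v[:, 0] - o[:, 0])

    d1 = cross(a, b, p)
    d2 = cross(b, c, p)
    d3 = cross(c, a, p)
    neg = (d1 < 0) | (d2 < 0) | (d3 < 0)
    pos = (d1 > 0) | (d2 > 0) | (d3 > 0)
    return ~(neg & pos)


def _coplanar_overlap(t1: np.ndarray, t2: np.ndarray, n: np.ndarray) -> np.ndarray:
    a = _project_coplanar(t1, n)
    b = _project_coplanar(t2, n)
    hit = np.zeros(len(t1), dtype=bool)
    for i in range(3):
        for j in range(3):
            hit |= _segments_intersect_2d(
                a[:, i], a[:, (i + 1) % 3], b[:, j], b[:, (j + 1) % 3]
            )
    hit |= _point_in_tri_2d(a[:, 0], b)
    hit |= _point_in_tri_2d(b[:, 0], a)
    return hit


def triangles_intersect(t1: np.ndarray, t2: np.ndarray, eps: float = 1e-12):
    """Pairwise proper-intersection test for (N,3,3) triangle arrays.

    Pairs that merely touch within ``eps`` (shared vertices/edges of
    adjacent mesh faces should be excluded by the caller) count as
    non-intersecting.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    n_pairs = len(t1)
    result = np.zeros(n_pairs, dtype=bool)
    if n_pairs == 0:
        return result

    n2 = np.cross(t2[:, 1] - t2[:, 0], t2[:, 2] - t2[:, 0])
    d2 = -np.einsum("ij,ij->i", n2, t2[:, 0])
    dv1 = np.einsum("nj,nkj->nk", n2, t1) + d2[:, None]
    scale = np.linalg.norm(n2, axis=1) + eps
    dv1n = dv1 / scale[:, None]
    same_side_1 = np.all(dv1n > eps, axis=1) | np.all(dv1n < -eps, axis=1)

    n1 = np.cross(t1[:, 1] - t1[:, 0], t1[:, 2] - t1[:, 0])
    d1 = -np.einsum("ij,ij->i", n1, t1[:, 0])
    dv2 = np.einsum("nj,nkj->nk", n1, t2) + d1[:, None]
    scale1 = np.linalg.norm(n1, axis=1) + eps
    dv2n = dv2 / scale1[:, None]
    same_side_2 = np.all(dv2n > eps, axis=1) | np.all(dv2n < -eps, axis=1)

    maybe = ~(same_side_1 | same_side_2)
    coplanar = maybe & np.all(np.abs(dv1n) <= eps, axis=1)
    crossing = maybe & ~coplanar
    if np.any(coplanar):
        result[coplanar] = _coplanar_overlap(
            t1[coplanar], t2[coplanar], n1[coplanar]
        )
    if not np.any(crossing):
        return result

    idx = np.where(crossing)[0]
    interval1 = _line_interval(t1[idx], dv1[idx], n1[idx], n2[idx], eps)
    interval2 = _line_interval(t2[idx], dv2[idx], n2[idx], n1[idx], eps)
    ok = ~(np.isnan(interval1).any(axis=1) | np.isnan(interval2).any(axis=1))
    lo = np.maximum(interval1[:, 0], interval2[:, 0])
    hi = np.minimum(interval1[:, 1], interval2[:, 1])
    span = np.maximum(
        interval1[:, 1] - interval1[:, 0], interval2[:, 1] - interval2[:, 0]
    )
    result[idx] = ok & (hi - lo > 1e-9 * (span + eps))
    return result


def _line_interval(tri, dv, n_self, n_other, eps):
    """Interval of a triangle on the intersection line of its plane with
    another plane.  dv: signed distances of the 3 vertices to the other
    plane.  Returns (N, 2) [lo, hi], NaN when degenerate."""
    direction = np.cross(n_self, n_other)
    axis = np.argmax(np.abs(direction), axis=1)
    proj = np.take_along_axis(tri, axis[:, None, None], axis=2)[:, :, 0]

    out = np.full((len(tri), 2), np.nan)
    # the vertex alone on its side of the other plane
    signs = np.sign(dv)
    for lone in range(3):
        o1, o2 = (lone + 1) % 3, (lone + 2) % 3
        m = (signs[:, lone] != signs[:, o1]) & (signs[:, lone] != signs[:, o2])
        m &= np.abs(dv[:, lone]) > 0
        if not np.any(m):
            continue
        t1 = proj[m, lone] + (proj[m, o1] - proj[m, lone]) * dv[m, lone] / (
            dv[m, lone] - dv[m, o1]
        )
        t2 = proj[m, lone] + (proj[m, o2] - proj[m, lone]) * dv[m, lone] / (
            dv[m, lone] - dv[m, o2]
        )
        out[m, 0] = np.minimum(t1, t2)
        out[m, 1] = np.maximum(t1, t2)
    # vertices exactly on the plane: treat the on-plane vertex as interval
    undone = np.isnan(out[:, 0])
    if np.any(undone):
        for v in range(3):
            m = undone & (np.abs(dv[:, v]) <= eps * 10)
            out[m, 0] = np.where(np.isnan(out[m, 0]), proj[m, v], np.minimum(out[m, 0], proj[m, v]))
            out[m, 1] = np.where(np.isnan(out[m, 1]), proj[m, v], np.maximum(out[m, 1], proj[m, v]))
    return out


def ray_parity_inside(point: np.ndarray, triangles: np.ndarray, rng=None) -> bool:
    """True when ``point`` is inside the closed surface ``triangles``
    ((M,3,3)) by ray-crossing parity.  A few random ray directions are
    tried to dodge edge-grazing degeneracies."""
    if rng is None:
        rng = np.random.default_rng(12345)
    p = np.asarray(point, dtype=float)
    v0, v1, v2 = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    for _ in range(8):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        h = np.cross(d, e2)
        a = np.einsum("ij,ij->i", e1, h)
        ok = np.abs(a) > 1e-12
        f = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
        s = p - v0
        u = f * np.einsum("ij,ij->i", s, h)
        q = np.cross(s, e1)
        v = f * (q @ d)
        t = f * np.einsum("ij,ij->i", e2, q)
        hit = ok & (u >= 0) & (u <= 1) & (v >= 0) & (u + v <= 1) & (t > 1e-12)
        # grazing: u/v suspiciously near triangle edges -> retry with new ray
        grazing = ok & (t > 1e-12) & (
            (np.abs(u) < 1e-9)
            | (np.abs(v) < 1e-9)
            | (np.abs(u + v - 1) < 1e-9)
        )
        if not np.any(grazing):
            return bool(np.count_nonzero(hit) % 2 == 1)
    return bool(np.count_nonzero(hit) % 2 == 1)
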