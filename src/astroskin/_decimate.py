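"""Quadric edge-collapse mesh decimation.

Garland-Heckbert error quadrics with lazy-deletion heap, link-condition
manifoldness checks and normal-flip rejection.  Pure numpy + heapq; the
initial per-edge costs are computed in one batched 3x3 solve, collapses are
then processed incrementally.
"""

from __future__ import annotations

import heapq

import numpy as np


def _face_quadrics(V: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Area-weighted fundamental quadric of every face, as (m, 4, 4)."""
    p0, p1, p2 = V[F[:, 0]], V[F[:, 1]], V[F[:, 2]]
    n = np.cross(p1 - p0, p2 - p0)
    norm = np.linalg.norm(n, axis=1)
    area = 0.5 * norm
    safe = np.where(norm == 0, 1.0, norm)
    n = n / safe[:, None]
    d = -np.einsum("ij,ij->i", n, p0)
    plane = np.concatenate([n, d[:, None]], axis=1)  # (m, 4)
    Q = plane[:, :, None] * plane[:, None, :]
    return Q * area[:, None, None]


def _optimal_point(Q: np.ndarray, v1: np.ndarray, v2: np.ndarray):
    """Optimal contraction target for a combined quadric; falls back to the
    best of (v1, mid, v2) when the 3x3 system is ill-conditioned."""
    A = Q[:3, :3]
    b = -Q[:3, 3]
    candidates = None
    try:
        if np.linalg.cond(A) < 1e8:
            x = np.linalg.solve(A, b)
            candidates = [x]
    except np.linalg.LinAlgError:
        pass
    if candidates is None:
        candidates = [v1, 0.5 * (v1 + v2), v2]
    best, best_cost = None, np.inf
    for x in candidates:
        h = np.append(x, 1.0)
        cost = float(h @ Q @ h)
        if cost < best_cost:
            best, best_cost = x, cost
    return best, max(best_cost, 0.0)


def _batch_edge_costs(Qv: np.ndarray, edges: np.ndarray, V: np.ndarray):
    """Vectorized initial cost + target for every edge."""
    Qe = Qv[edges[:, 0]] + Qv[edges[:, 1]]
    A = Qe[:, :3, :3]
    b = -Qe[:, :3, 3]
    det = np.linalg.det(A)
    good = np.abs(det) > 1e-10
    X = np.empty((len(edges), 3))
    if np.any(good):
        X[good] = np.linalg.solve(A[good], b[good][..., None])[..., 0]
    mid = 0.5 * (V[edges[:, 0]] + V[edges[:, 1]])
    X[~good] = mid[~good]
    # reject optimal points that fly far away from the edge
    span = np.linalg.norm(V[edges[:, 0]] - V[edges[:, 1]], axis=1) + 1e-12
    far = np.linalg.norm(X - mid, axis=1) > 4.0 * span
    X[far] = mid[far]
    h = np.concatenate([X, np.ones((len(edges), 1))], axis=1)
    cost = np.einsum("ni,nij,nj->n", h, Qe, h)
    return np.maximum(cost, 0.0), X


class _Mesh:
    """Mutable adjacency for the collapse loop."""

    def __init__(self, V, F):
        self.V = V.copy()
        self.F = F.copy()
        self.face_alive = np.ones(len(F), dtype=bool)
        self.vfaces = [set() for _ in range(len(V))]
        for fi, f in enumerate(F):
            for v in f:
                self.vfaces[v].add(fi)

    def neighbors(self, v: int) -> set:
        out = set()
        for fi in self.vfaces[v]:
            out.update(self.F[fi])
        out.discard(v)
        return out


def decimate_quadric(
    V: np.ndarray,
    F: np.ndarray,
    target_faces: int,
    preserve_boundary: bool = True,
):
    """Collapse edges until ``target_faces`` remain (or no valid collapse).

    Returns ``(V_out, F_out, achieved_faces)``.  Collapses that would
    produce a non-manifold configuration (link condition) or flip a face
    normal are rejected.
    """
    V = np.asarray(V, dtype=float)
    F = np.asarray(F, dtype=np.int64)
    mesh = _Mesh(V, F)
    Qv = np.zeros((len(V), 4, 4))
    Qf = _face_quadrics(V, F)
    for k in range(3):
        np.add.at(Qv, F[:, k], Qf)

    edges = np.unique(np.sort(np.vstack([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]]), axis=1), axis=0)

    boundary_verts = np.zeros(len(V), dtype=bool)
    e_all = np.sort(np.vstack([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(e_all, axis=0, return_counts=True)
    b_edges = uniq[counts == 1]
    boundary_verts[b_edges.ravel()] = True

    cost, X = _batch_edge_costs(Qv, edges, V)
    version = np.zeros(len(V), dtype=np.int64)
    heap = []
    for i, (u, v) in enumerate(edges):
        heapq.heappush(heap, (cost[i], int(u), int(v), 0, 0, X[i]))

    n_alive = len(F)
    vertex_alive = np.ones(len(V), dtype=bool)

    def push_edge(u, v):
        if u == v or not (vertex_alive[u] and vertex_alive[v]):
            return
        a, b = (u, v) if u < v else (v, u)
        Qe = Qv[a] + Qv[b]
        x, c = _optimal_point(Qe, mesh.V[a], mesh.V[b])
        heapq.heappush(heap, (c, a, b, int(version[a]), int(version[b]), x))

    while n_alive > target_faces and heap:
        c, u, v, vu, vv, x = heapq.heappop(heap)
        if not (vertex_alive[u] and vertex_alive[v]):
            continue
        if version[u] != vu or version[v] != vv:
            continue
        if v not in mesh.neighbors(u):
            continue
        if preserve_boundary and (boundary_verts[u] or boundary_verts[v]):
            continue

        # link condition: shared neighbors must be exactly the opposite
        # vertices of the faces shared by edge (u, v)
        nu = mesh.neighbors(u)
        nv = mesh.neighbors(v)
        shared_faces = mesh.vfaces[u] & mesh.vfaces[v]
        if len(shared_faces) != 2:
            continue
        wing = set()
        for fi in shared_faces:
            for w in mesh.F[fi]:
                if w != u and w != v:
                    wing.add(int(w))
        if (nu & nv) != wing:
            continue

        # normal-flip / degeneracy check on surviving faces around u and v
        affected = (mesh.vfaces[u] | mesh.vfaces[v]) - shared_faces
        flip = False
        for fi in affected:
            f = mesh.F[fi]
            old = [mesh.V[w] for w in f]
            new = [x if (w == u or w == v) else mesh.V[w] for w in f]
            n_old = np.cross(old[1] - old[0], old[2] - old[0])
            n_new = np.cross(new[1] - new[0], new[2] - new[0])
            nn = np.linalg.norm(n_new)
            if nn < 1e-14 or np.dot(n_old, n_new) <= 0:
                flip = True
                break
        if flip:
            continue

        # collapse v into u at position x
        mesh.V[u] = x
        Qv[u] = Qv[u] + Qv[v]
        vertex_alive[v] = False
        for fi in shared_faces:
            if mesh.face_alive[fi]:
                mesh.face_alive[fi] = False
                n_alive -= 1
            for w in mesh.F[fi]:
                mesh.vfaces[w].discard(fi)
        for fi in list(mesh.vfaces[v]):
            f = mesh.F[fi]
            mesh.F[fi] = np.where(f == v, u, f)
            mesh.vfaces[u].add(fi)
        mesh.vfaces[v] = set()
        version[u] += 1
        version[v] += 1

        for w in nu | nv:
            if w != u and vertex_alive[w]:
                push_edge(u, int(w))

    keep = mesh.face_alive
    F_out = mesh.F[keep]
    used = np.unique(F_out)
    remap = np.full(len(mesh.V), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return mesh.V[used], remap[F_out], int(n_alive)
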