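"""Post-polygonization mesh processing and QC.

Partition handling, manifoldness accounting, self-intersection detection,
quadric decimation, watertight repair and the Metro-style RMS Hausdorff
metric.  Meshes are ``trimesh.Trimesh`` objects throughout; areas are µm²,
volumes µm³.

Watertight here means: a single partition, every edge in exactly two faces,
zero non-manifold edges and vertices, and zero self-intersections — the
requirement for downstream tetrahedralization (TetGen / Quartet / TetWild),
which is the hand-off point of this package.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from astroskin._decimate import decimate_quadric
from astroskin._geom import MeshProximity, ray_parity_inside, triangles_intersect


@dataclass
class MeshQCReport:
    partition_count: int
    non_manifold_edges: int
    non_manifold_vertices: int
    boundary_edges: int
    self_intersections: int | None
    surface_area: float
    volume: float | None
    n_vertices: int
    n_triangles: int

    @property
    def watertight(self) -> bool:
        return (
            self.partition_count == 1
            and self.non_manifold_edges == 0
            and self.non_manifold_vertices == 0
            and self.boundary_edges == 0
            and (self.self_intersections or 0) == 0
        )

    def to_json(self, path=None) -> str:
        doc = asdict(self)
        doc["watertight"] = self.watertight
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _sorted_edges(faces: np.ndarray) -> np.ndarray:
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    return np.sort(e, axis=1)


def split_partitions(mesh: trimesh.Trimesh) -> list[trimesh.Trimesh]:
    """Connected components by shared vertices, ordered by descending
    enclosed volume (open components afterwards, by descending area)."""
    V, F = mesh.vertices, mesh.faces
    if len(F) == 0:
        return []
    edges = _sorted_edges(F)
    adj = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(len(V), len(V))
    )
    n_comp, labels = connected_components(adj, directed=False)
    face_label = labels[F[:, 0]]
    parts = []
    for ci in range(n_comp):
        fsel = F[face_label == ci]
        if len(fsel) == 0:
            continue  # isolated vertices
        used = np.unique(fsel)
        remap = np.full(len(V), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        part = trimesh.Trimesh(vertices=V[used], faces=remap[fsel], process=False)
        parts.append(part)

    def key(p: trimesh.Trimesh):
        closed = bool(p.is_winding_consistent and p.is_watertight)
        vol = abs(p.volume) if closed else 0.0
        return (0 if closed else 1, -vol, -p.area)

    parts.sort(key=key)
    return parts


def count_non_manifold(mesh: trimesh.Trimesh) -> tuple[int, int]:
    """(non-manifold edge count, non-manifold vertex count).

    An edge is non-manifold when more than two faces share it; boundary
    edges (exactly one face) are not counted here.  A vertex is
    non-manifold when its incident faces, linked through edges at that
    vertex, form more than one connected fan.
    """
    F = np.asarray(mesh.faces)
    if len(F) == 0:
        return 0, 0
    edges = _sorted_edges(F)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    nm_edges = int(np.count_nonzero(counts > 2))

    # fan connectivity per vertex
    n_v = len(mesh.vertices)
    incident: list[list[int]] = [[] for _ in range(n_v)]
    for fi, f in enumerate(F):
        for v in f:
            incident[v].append(fi)
    nm_vertices = 0
    for v in range(n_v):
        faces_v = incident[v]
        if len(faces_v) <= 1:
            continue
        # faces adjacent iff they share an edge containing v, i.e. share
        # one of the two "other" vertices
        other: dict[int, list[int]] = {}
        for fi in faces_v:
            for w in F[fi]:
                if w != v:
                    other.setdefault(int(w), []).append(fi)
        parent = {fi: fi for fi in faces_v}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for group in other.values():
            for fi in group[1:]:
                ra, rb = find(group[0]), find(fi)
                if ra != rb:
                    parent[ra] = rb
        roots = {find(fi) for fi in faces_v}
        if len(roots) > 1:
            nm_vertices += 1
    return nm_edges, nm_vertices


def boundary_edge_count(mesh: trimesh.Trimesh) -> int:
    F = np.asarray(mesh.faces)
    if len(F) == 0:
        return 0
    uniq, counts = np.unique(_sorted_edges(F), axis=0, return_counts=True)
    return int(np.count_nonzero(counts == 1))


def detect_self_intersections(
    mesh: trimesh.Trimesh, brute_force: bool = False, chunk: int = 200_000
) -> int:
    """Count geometrically intersecting, non-adjacent triangle pairs.

    The default path prunes candidate pairs with a KD-tree over triangle
    centroids; ``brute_force=True`` tests all pairs and must agree.
    """
    tris = np.asarray(mesh.triangles)
    F = np.asarray(mesh.faces)
    n = len(tris)
    if n < 2:
        return 0
    if brute_force:
        ii, jj = np.triu_indices(n, k=1)
        pairs = np.stack([ii, jj], axis=1)
    else:
        centroids = tris.mean(axis=1)
        reach = np.linalg.norm(tris - centroids[:, None, :], axis=2).max(axis=1)
        tree = cKDTree(centroids)
        raw = tree.query_pairs(r=2.0 * float(reach.max()), output_type="ndarray")
        pairs = raw
    if len(pairs) == 0:
        return 0
    # exclude adjacent faces (sharing any vertex)
    fa, fb = F[pairs[:, 0]], F[pairs[:, 1]]
    shares = (fa[:, :, None] == fb[:, None, :]).any(axis=(1, 2))
    pairs = pairs[~shares]
    count = 0
    for s in range(0, len(pairs), chunk):
        block = pairs[s : s + chunk]
        hit = triangles_intersect(tris[block[:, 0]], tris[block[:, 1]])
        count += int(np.count_nonzero(hit))
    return count


def remove_interior_partition(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Drop the nested partition of a two-partition closed mesh.

    The partition with fewer triangles is removed (ties broken by smaller
    enclosed volume) after verifying by ray parity that it lies inside the
    other.  Raises ValueError when the mesh does not have exactly two
    nested closed partitions.
    """
    parts = split_partitions(mesh)
    if len(parts) != 2:
        raise ValueError(
            f"expected exactly 2 partitions, found {len(parts)} "
            f"(face counts: {[len(p.faces) for p in parts]})"
        )
    a, b = parts
    if len(a.faces) == len(b.faces):
        inner = a if abs(a.volume) < abs(b.volume) else b
    else:
        inner = a if len(a.faces) < len(b.faces) else b
    outer = b if inner is a else a
    probe = inner.vertices[0]
    if not ray_parity_inside(probe, np.asarray(outer.triangles)):
        raise ValueError("partitions are not nested: smaller one is not inside")
    return outer


def decimate(mesh: trimesh.Trimesh, ratio: float) -> trimesh.Trimesh:
    """Quadric edge-collapse decimation to ``ratio`` of the face count.

    Stops early (reporting the achieved ratio via the returned mesh's face
    count) when no further collapse preserves manifoldness.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    target = max(4, int(np.ceil(ratio * len(mesh.faces))))
    V, F, achieved = decimate_quadric(
        np.asarray(mesh.vertices), np.asarray(mesh.faces), target
    )
    return trimesh.Trimesh(vertices=V, faces=F, process=False)


def _merge_duplicate_vertices(
    mesh: trimesh.Trimesh, tol: float = 1e-6
) -> trimesh.Trimesh:
    V = np.asarray(mesh.vertices)
    F = np.asarray(mesh.faces)
    keys = np.round(V / tol).astype(np.int64)
    _, first, inverse = np.unique(
        keys, axis=0, return_index=True, return_inverse=True
    )
    return trimesh.Trimesh(vertices=V[first], faces=inverse[F], process=False)


def _drop_degenerate(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    F = np.asarray(mesh.faces)
    ok = (F[:, 0] != F[:, 1]) & (F[:, 1] != F[:, 2]) & (F[:, 0] != F[:, 2])
    m = trimesh.Trimesh(vertices=mesh.vertices, faces=F[ok], process=False)
    areas = m.area_faces
    if np.any(areas <= 0):
        m.update_faces(areas > 0)
    # duplicated faces (same vertex set) break manifoldness
    Fs = np.sort(np.asarray(m.faces), axis=1)
    _, first = np.unique(Fs, axis=0, return_index=True)
    if len(first) != len(Fs):
        m = trimesh.Trimesh(
            vertices=m.vertices, faces=np.asarray(m.faces)[np.sort(first)],
            process=False,
        )
    return m


def _remove_fins(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Iteratively drop extra faces on over-shared edges (keep the two
    largest by area)."""
    m = mesh
    for _ in range(16):
        F = np.asarray(m.faces)
        edges = _sorted_edges(F)
        uniq, inv, counts = np.unique(
            edges, axis=0, return_inverse=True, return_counts=True
        )
        if not np.any(counts > 2):
            return m
        areas = m.area_faces
        face_of_edge = np.tile(np.arange(len(F)), 3)
        # per-face count of boundary edges: a dangling fin hangs off the
        # over-shared edge by its one attached edge, the rest are boundary
        edge_count_of = counts[inv]  # per directed-edge row
        boundary_edges_per_face = (
            (edge_count_of.reshape(3, -1) == 1).sum(axis=0)
        )
        drop = set()
        for ei in np.where(counts > 2)[0]:
            fids = face_of_edge[inv == ei]
            # drop loose faces first (most boundary edges), then smallest
            order = np.lexsort((areas[fids], -boundary_edges_per_face[fids]))
            for fi in fids[order[: len(fids) - 2]]:
                drop.add(int(fi))
        keep = np.ones(len(F), dtype=bool)
        keep[list(drop)] = False
        m = trimesh.Trimesh(vertices=m.vertices, faces=F[keep], process=False)
    return m


def _boundary_loops(mesh: trimesh.Trimesh) -> list[list[int]]:
    F = np.asarray(mesh.faces)
    edges = _sorted_edges(F)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    bedges = uniq[counts == 1]
    if len(bedges) == 0:
        return []
    nxt: dict[int, list[int]] = {}
    for u, v in bedges:
        nxt.setdefault(int(u), []).append(int(v))
        nxt.setdefault(int(v), []).append(int(u))
    unused = {tuple(e) for e in bedges}
    loops = []
    while unused:
        u, v = next(iter(unused))
        unused.discard((u, v))
        loop = [u, v]
        while True:
            cands = [w for w in nxt[loop[-1]] if tuple(sorted((loop[-1], w))) in unused]
            if not cands:
                break
            w = cands[0]
            unused.discard(tuple(sorted((loop[-1], w))))
            if w == loop[0]:
                break
            loop.append(w)
        if len(loop) >= 3:
            loops.append(loop)
    return loops


def _fill_holes(mesh: trimesh.Trimesh, max_loop: int = 10_000) -> trimesh.Trimesh:
    """Triangulate each boundary loop with a centroid fan, oriented to
    match the winding of the adjacent faces."""
    loops = _boundary_loops(mesh)
    if not loops:
        return mesh
    V = np.asarray(mesh.vertices)
    F = np.asarray(mesh.faces)
    # directed boundary edges as they appear in faces: (u->v) means face
    # winding traverses u->v, so the fill must traverse v->u
    directed = set()
    edges_dir = np.vstack([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]])
    s = np.sort(edges_dir, axis=1)
    uniq, inv, counts = np.unique(s, axis=0, return_inverse=True, return_counts=True)
    for k in np.where(counts[inv] == 1)[0]:
        directed.add((int(edges_dir[k, 0]), int(edges_dir[k, 1])))
    new_v = [V]
    new_f = [F]
    base = len(V)
    for loop in loops:
        if len(loop) > max_loop:
            continue  # unfillable; reported by the caller via QC
        centroid = V[loop].mean(axis=0)
        new_v.append(centroid[None, :])
        ci = base
        base += 1
        tris = []
        for u, v in zip(loop, loop[1:] + loop[:1]):
            if (u, v) in directed:
                tris.append([v, u, ci])
            else:
                tris.append([u, v, ci])
        new_f.append(np.array(tris, dtype=np.int64))
    return trimesh.Trimesh(
        vertices=np.vstack(new_v), faces=np.vstack(new_f), process=False
    )


def repair_watertight(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Best-effort watertight repair.

    Pipeline: merge duplicate vertices (1e-6 µm) -> drop degenerate and
    duplicate faces -> remove non-manifold fins -> fill boundary loops with
    centroid fans -> enforce coherent outward orientation -> keep the
    largest partition.  Idempotent on meshes it successfully repairs;
    residual defects show up in :func:`mesh_metrics`.
    """
    m = _merge_duplicate_vertices(mesh)
    m = _drop_degenerate(m)
    m = _remove_fins(m)
    m = _fill_holes(m)
    parts = split_partitions(m)
    if parts:
        m = parts[0]
    trimesh.repair.fix_normals(m)
    if m.is_watertight and m.volume < 0:
        m.invert()
    return m


def mesh_metrics(
    mesh: trimesh.Trimesh, check_self_intersections: bool = True
) -> MeshQCReport:
    """Full QC report: partitions, manifoldness, area/volume,
    self-intersections (optional — the expensive part)."""
    parts = split_partitions(mesh)
    nm_e, nm_v = count_non_manifold(mesh)
    b_e = boundary_edge_count(mesh)
    closed = b_e == 0 and nm_e == 0
    vol = None
    if closed:
        mm = mesh.copy()
        if not mm.is_winding_consistent:
            trimesh.repair.fix_normals(mm)
        vol = float(abs(mm.volume))
    si = (
        detect_self_intersections(mesh) if check_self_intersections else None
    )
    return MeshQCReport(
        partition_count=len(parts),
        non_manifold_edges=nm_e,
        non_manifold_vertices=nm_v,
        boundary_edges=b_e,
        self_intersections=si,
        surface_area=float(mesh.area),
        volume=vol,
        n_vertices=len(mesh.vertices),
        n_triangles=len(mesh.faces),
    )


def hausdorff_rms(
    a: trimesh.Trimesh,
    b: trimesh.Trimesh,
    samples: int = 100_000,
    seed: int = 0,
) -> float:
    """Symmetric RMS point-to-surface distance, Metro convention.

    ``samples`` area-weighted random points are drawn on each mesh; RMS is
    taken over both directions pooled and normalized by the bounding-box
    diagonal of ``a``.
    """
    pa, _ = trimesh.sample.sample_surface(a, samples, seed=seed)
    pb, _ = trimesh.sample.sample_surface(b, samples, seed=seed + 1)
    d_ab = MeshProximity(b).distance(pa)
    d_ba = MeshProximity(a).distance(pb)
    rms = float(np.sqrt(np.mean(np.concatenate([d_ab, d_ba]) ** 2)))
    diag = float(np.linalg.norm(a.bounds[1] - a.bounds[0]))
    return rms / diag


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    """Write OBJ / PLY / OFF / STL by extension."""
    mesh.export(path)


def read_mesh(path) -> trimesh.Trimesh:
    m = trimesh.load_mesh(path, process=False)
    return m
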