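"""Uniform isotropic remeshing.

Classic incremental remeshing (Botsch-Kobbelt style): per iteration, split
edges longer than 4/3 of the target length (conforming midpoint splits, so
no T-junctions), collapse edges shorter than 4/5 of the target, flip
interior edges toward valence 6, then relax vertices tangentially and
re-project them onto the original surface. Five iterations land the median
edge length within a few percent of the target while keeping the maximum
one-sided deviation from the input surface well below half the target edge.

Closed surfaces stay closed; meshes with open boundaries (partial-bone
cuts) are supported — boundary edges are split but never collapsed or
flipped, and boundary vertices are not relaxed, so the boundary polygon is
only refined, never eroded.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .geometry import closest_point_on_mesh
from .mesh import TriangleMesh

__all__ = ["remesh_uniform", "NonManifoldError"]


class NonManifoldError(ValueError):
    """Input mesh is not manifold; message lists the defects."""


def _edge_face_count(faces: np.ndarray) -> dict:
    counts: dict[tuple[int, int], int] = {}
    for f in faces:
        for k in range(3):
            a, b = int(f[k]), int(f[(k + 1) % 3])
            e = (a, b) if a < b else (b, a)
            counts[e] = counts.get(e, 0) + 1
    return counts


def _check_manifold(mesh: TriangleMesh) -> bool:
    """Validate edge-manifoldness and winding; returns True if closed."""
    tm = mesh.as_trimesh()
    counts = _edge_face_count(mesh.faces)
    over = sum(1 for c in counts.values() if c > 2)
    defects = []
    if over:
        defects.append(f"{over} edges shared by more than two faces")
    if not tm.is_winding_consistent:
        defects.append("inconsistent face winding")
    if defects:
        raise NonManifoldError("; ".join(defects))
    return all(c == 2 for c in counts.values())


def _boundary_vertices(faces: np.ndarray, n_vertices: int) -> np.ndarray:
    counts = _edge_face_count(faces)
    flag = np.zeros(n_vertices, dtype=bool)
    for (a, b), c in counts.items():
        if c == 1:
            flag[a] = flag[b] = True
    return flag


def _split_pass(verts: np.ndarray, faces: np.ndarray, max_len: float):
    """Conforming midpoint split of every edge longer than ``max_len``.

    Faces are re-triangulated per the number of split edges (1 -> 2,
    2 -> 3, 3 -> 4 triangles), sharing midpoints through an edge registry so
    the result has no cracks."""
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    eu = np.unique(e, axis=0)
    lengths = np.linalg.norm(verts[eu[:, 0]] - verts[eu[:, 1]], axis=1)
    long_edges = eu[lengths > max_len]
    if len(long_edges) == 0:
        return verts, faces, 0
    mid_index = {}
    new_verts = [verts]
    next_id = len(verts)
    for a, b in long_edges:
        mid_index[(int(a), int(b))] = next_id
        next_id += 1
    new_verts.append(0.5 * (verts[long_edges[:, 0]] + verts[long_edges[:, 1]]))
    verts_out = np.vstack(new_verts)

    def mid(a, b):
        return mid_index.get((a, b) if a < b else (b, a))

    out_faces = []
    for f in faces:
        a, b, c = int(f[0]), int(f[1]), int(f[2])
        mab, mbc, mca = mid(a, b), mid(b, c), mid(c, a)
        n_split = sum(m is not None for m in (mab, mbc, mca))
        if n_split == 0:
            out_faces.append((a, b, c))
        elif n_split == 3:
            out_faces += [(a, mab, mca), (mab, b, mbc), (mca, mbc, c), (mab, mbc, mca)]
        elif n_split == 1:
            # rotate so the split edge is (a, b)
            if mbc is not None:
                a, b, c, mab = b, c, a, mbc
            elif mca is not None:
                a, b, c, mab = c, a, b, mca
            out_faces += [(a, mab, c), (mab, b, c)]
        else:  # two split edges; rotate so the un-split edge is (c, a)
            if mab is None:
                a, b, c, mab, mbc = b, c, a, mbc, mca
            elif mbc is None:
                a, b, c, mab, mbc = c, a, b, mca, mab
            out_faces += [(a, mab, c), (mab, mbc, c), (mab, b, mbc)]
    return verts_out, np.asarray(out_faces, dtype=np.int64), len(long_edges)


def _collapse_pass(verts: np.ndarray, faces: np.ndarray, min_len: float, max_len: float):
    """One greedy pass of short-edge collapses to edge midpoints.

    A collapse must satisfy the link condition (endpoints share exactly two
    neighbors for interior edges, one for boundary edges), must not mix a
    boundary vertex into the interior, and must not create an edge longer
    than ``max_len``. Returns (verts, faces, n_collapsed)."""
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    edges = np.unique(e, axis=0)
    lengths = np.linalg.norm(verts[edges[:, 0]] - verts[edges[:, 1]], axis=1)
    short = np.where(lengths < min_len)[0]
    if len(short) == 0:
        return verts, faces, 0
    short = short[np.argsort(lengths[short])]

    neighbors = [set() for _ in range(len(verts))]
    for u, v in edges:
        neighbors[u].add(int(v))
        neighbors[v].add(int(u))
    counts = _edge_face_count(faces)
    boundary = _boundary_vertices(faces, len(verts))

    pos = verts.copy()
    merge_to = np.arange(len(verts))
    touched = np.zeros(len(verts), dtype=bool)
    n_done = 0
    for ei in short:
        u, v = int(edges[ei, 0]), int(edges[ei, 1])
        if touched[u] or touched[v]:
            continue
        if boundary[u] != boundary[v]:
            continue  # never drag the boundary into the interior
        edge_key = (u, v)
        on_boundary_edge = counts.get(edge_key, 0) == 1
        if boundary[u] and boundary[v] and not on_boundary_edge:
            continue  # chord between two boundary points would pinch the hole
        common = neighbors[u] & neighbors[v]
        if len(common) != (1 if on_boundary_edge else 2):
            continue
        mid = 0.5 * (pos[u] + pos[v])
        ring = (neighbors[u] | neighbors[v]) - {u, v}
        if ring and np.linalg.norm(pos[list(ring)] - mid, axis=1).max() > max_len:
            continue
        pos[u] = mid
        merge_to[v] = u
        touched[u] = touched[v] = True
        for w in ring:
            touched[w] = True
        n_done += 1
    if n_done == 0:
        return verts, faces, 0

    faces2 = merge_to[faces]
    keep = (
        (faces2[:, 0] != faces2[:, 1])
        & (faces2[:, 1] != faces2[:, 2])
        & (faces2[:, 0] != faces2[:, 2])
    )
    faces2 = faces2[keep]
    key = np.sort(faces2, axis=1)
    _, first = np.unique(key, axis=0, return_index=True)
    faces2 = faces2[np.sort(first)]
    used = np.unique(faces2)
    remap = np.full(len(pos), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return pos[used], remap[faces2], n_done


def _flip_pass(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip interior edges when doing so reduces total deviation from the
    regular valence (6 interior, 4 boundary) without folding triangles."""
    faces = faces.copy()
    edge_map: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for fi, f in enumerate(faces):
        for k in range(3):
            a, b = int(f[k]), int(f[(k + 1) % 3])
            edge_map.setdefault((min(a, b), max(a, b)), []).append((fi, k))
    valence = np.zeros(len(verts), dtype=np.int64)
    for (a, b) in edge_map:
        valence[a] += 1
        valence[b] += 1
    boundary = _boundary_vertices(faces, len(verts))
    target = np.where(boundary, 4, 6)
    existing = set(edge_map)
    face_used = np.zeros(len(faces), dtype=bool)

    for (a, b), occ in edge_map.items():
        if len(occ) != 2:
            continue
        (f1, k1), (f2, k2) = occ
        if face_used[f1] or face_used[f2]:
            continue
        c = int(faces[f1][(k1 + 2) % 3])
        d = int(faces[f2][(k2 + 2) % 3])
        if c == d or (min(c, d), max(c, d)) in existing:
            continue
        dev = lambda: sum(abs(valence[i] - target[i]) for i in (a, b, c, d))
        before = dev()
        valence[a] -= 1
        valence[b] -= 1
        valence[c] += 1
        valence[d] += 1
        after = dev()

        def undo():
            valence[a] += 1
            valence[b] += 1
            valence[c] -= 1
            valence[d] -= 1

        if after >= before:
            undo()
            continue
        # orientation: f1 holds directed edge u->v at slot k1 (opposite c),
        # f2 holds v->u (opposite d); the new faces keep the four boundary
        # directed edges, so winding stays consistent.
        u, v = int(faces[f1][k1]), int(faces[f1][(k1 + 1) % 3])
        new1 = np.array([c, u, d])
        new2 = np.array([d, v, c])
        n_old = np.cross(verts[v] - verts[u], verts[c] - verts[u])
        ref = n_old / (np.linalg.norm(n_old) + 1e-30)
        n_new1 = np.cross(verts[new1[1]] - verts[new1[0]], verts[new1[2]] - verts[new1[0]])
        n_new2 = np.cross(verts[new2[1]] - verts[new2[0]], verts[new2[2]] - verts[new2[0]])
        if (n_new1 @ ref) <= 1e-12 or (n_new2 @ ref) <= 1e-12:
            undo()
            continue
        faces[f1] = new1
        faces[f2] = new2
        face_used[f1] = face_used[f2] = True
        existing.discard((a, b))
        existing.add((min(c, d), max(c, d)))
    return faces


def _relax_and_project(verts, faces, src_verts, src_faces, src_tree, damping=0.5):
    tm = trimesh.Trimesh(verts, faces, process=False)
    normals = np.asarray(tm.vertex_normals)
    boundary = _boundary_vertices(faces, len(verts))
    nbr = tm.vertex_neighbors
    lap = np.zeros_like(verts)
    for i, ns in enumerate(nbr):
        if ns and not boundary[i]:
            lap[i] = verts[list(ns)].mean(axis=0) - verts[i]
    tangential = lap - (np.einsum("ij,ij->i", lap, normals))[:, None] * normals
    moved = verts + damping * tangential
    projected, _, _ = closest_point_on_mesh(src_verts, src_faces, moved, tree=src_tree)
    projected[boundary] = verts[boundary]  # boundary polygon is kept verbatim
    return projected


def remesh_uniform(
    mesh: TriangleMesh,
    target_edge: float = 2.0,
    n_iterations: int = 5,
    project: bool = True,
) -> TriangleMesh:
    """Remesh a manifold surface to a uniform target edge length (mm).

    Raises ``ValueError`` for a non-positive target or a target exceeding
    the mesh bounding box, and :class:`NonManifoldError` (listing defects)
    for non-manifold or inconsistently wound input. A closed input yields a
    closed output; an open boundary is preserved.
    """
    if target_edge <= 0:
        raise ValueError(f"target edge length must be positive, got {target_edge}")
    was_closed = _check_manifold(mesh)
    bbox = np.ptp(mesh.vertices, axis=0)
    if target_edge > bbox.max():
        raise ValueError(
            f"target edge {target_edge} mm exceeds the mesh bounding box {bbox}; "
            "refusing to produce a degenerate mesh"
        )

    src_verts = mesh.vertices.copy()
    src_faces = mesh.faces.copy()
    src_tree = cKDTree(src_verts)
    verts, faces = src_verts.copy(), src_faces.copy()
    long_thresh = 4.0 / 3.0 * target_edge
    short_thresh = 4.0 / 5.0 * target_edge

    for _ in range(n_iterations):
        for _pass in range(10):
            verts, faces, n = _split_pass(verts, faces, long_thresh)
            if n == 0:
                break
        for _pass in range(10):
            verts, faces, n = _collapse_pass(verts, faces, short_thresh, long_thresh)
            if n == 0:
                break
        faces = _flip_pass(verts, faces)
        if project:
            verts = _relax_and_project(verts, faces, src_verts, src_faces, src_tree)

    out = TriangleMesh(verts, faces, name=mesh.name, side=mesh.side, aligned=mesh.aligned)
    if was_closed and out.enclosed_volume() < 0:
        out = TriangleMesh(out.vertices, out.faces[:, ::-1], name=mesh.name, side=mesh.side, aligned=mesh.aligned)
    return out
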