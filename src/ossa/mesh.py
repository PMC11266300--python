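"""Triangle-mesh container and file I/O.

The :class:`TriangleMesh` is the universal currency of the pipeline: every
stage (segmentation output, remeshing, anatomical alignment, correspondence,
mode-shape synthesis) consumes and produces one. Coordinates are always in
millimetres. File I/O goes through trimesh (STL binary/ascii, PLY
binary/ascii, OBJ).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh

__all__ = ["TriangleMesh", "MeshIOError", "read_mesh", "write_mesh"]

_FORMATS = {"stl", "ply", "obj"}

# tolerance for merging duplicated per-facet vertices on read, mm
_MERGE_TOL = 1e-6


class MeshIOError(IOError):
    """Raised for unreadable, unwritable or structurally invalid mesh files."""


@dataclass
class TriangleMesh:
    """A triangle surface mesh in mm world coordinates.

    Parameters
    ----------
    vertices : (P, 3) float array
    faces : (F, 3) int array of vertex indices
    name : optional specimen / bone identifier
    side : optional ``"left"`` or ``"right"`` tag
    aligned : True once the mesh has been expressed in an anatomical frame;
        operations that require anatomical alignment (partial-bone cuts,
        correspondence) check this flag.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: Optional[str] = None
    side: Optional[str] = None
    aligned: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError(f"vertices must be (P, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError(f"faces must be (F, 3), got {self.faces.shape}")
        if not np.isfinite(self.vertices).all():
            raise ValueError("vertex coordinates must be finite")
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face index out of range")
            degenerate = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if degenerate.any():
                raise ValueError(f"{degenerate.sum()} degenerate faces (repeated indices)")
        if self.side is not None and self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    # -- basic descriptors -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def centroid_size(self) -> float:
        """RMS distance of vertices from their centroid (the scale measure
        used for median-template selection)."""
        d = self.vertices - self.centroid()
        return float(np.sqrt((d * d).sum(axis=1).mean()))

    def edge_lengths(self) -> np.ndarray:
        """Lengths of unique edges, mm."""
        tm = self.as_trimesh()
        e = tm.edges_unique
        d = self.vertices[e[:, 0]] - self.vertices[e[:, 1]]
        return np.linalg.norm(d, axis=1)

    # -- conversions -------------------------------------------------------
    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, **kw) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), **kw)

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same connectivity, new vertex positions."""
        return replace(self, vertices=np.asarray(vertices, dtype=np.float64))

    # -- topology checks ---------------------------------------------------
    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    def is_manifold(self) -> bool:
        tm = self.as_trimesh()
        return bool(tm.is_watertight and tm.is_winding_consistent)

    def euler_characteristic(self) -> int:
        tm = self.as_trimesh()
        return int(tm.euler_number)

    def enclosed_volume(self) -> float:
        """Signed enclosed volume, mm^3 (positive for outward orientation)."""
        return float(self.as_trimesh().volume)

    def area(self) -> float:
        return float(self.as_trimesh().area)


def _infer_format(path: Path, format: Optional[str]) -> str:
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise MeshIOError(f"unknown mesh format {fmt!r} for {path} (expected stl/ply/obj)")
    return fmt


def read_mesh(path, format: Optional[str] = None, merge_tol: float = _MERGE_TOL) -> TriangleMesh:
    """Read an STL/PLY/OBJ mesh.

    Duplicate vertices (e.g. STL's per-facet vertex soup) are merged within
    ``merge_tol`` mm. Raises :class:`MeshIOError` on missing/corrupt files or
    out-of-range face indices.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.is_file():
        raise MeshIOError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # trimesh raises a zoo of exception types
        raise MeshIOError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.vertices) == 0:
        raise MeshIOError(f"{path} contains no triangle geometry")
    verts = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if len(faces) and faces.max() >= len(verts):
        raise MeshIOError(f"{path}: face index {faces.max()} out of range for {len(verts)} vertices")
    verts, faces = _merge_close_vertices(verts, faces, merge_tol)
    try:
        return TriangleMesh(verts, faces)
    except ValueError as exc:
        raise MeshIOError(f"{path}: {exc}") from exc


def _merge_close_vertices(verts: np.ndarray, faces: np.ndarray, tol: float):
    """Merge vertices closer than ``tol`` by grid rounding (brute-force
    equivalent for well-separated meshes)."""
    if tol <= 0 or len(verts) == 0:
        return verts, faces
    key = np.round(verts / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    verts2 = verts[first]
    faces2 = inverse[faces]
    keep = ~(
        (faces2[:, 0] == faces2[:, 1])
        | (faces2[:, 1] == faces2[:, 2])
        | (faces2[:, 0] == faces2[:, 2])
    )
    return verts2, faces2[keep]


def write_mesh(mesh: TriangleMesh, path, format: Optional[str] = None, encoding: str = "binary") -> Path:
    """Write a mesh to STL/PLY/OBJ. ``encoding`` selects binary or ascii
    where the format supports both. Output is bit-stable for fixed input."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if mesh.n_vertices == 0 or mesh.n_faces == 0:
        raise MeshIOError("refusing to write an empty mesh")
    tm = mesh.as_trimesh()
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "ply":
        data = trimesh.exchange.ply.export_ply(
            tm, encoding="binary_little_endian" if encoding == "binary" else "ascii"
        )
    elif fmt == "stl":
        if encoding == "ascii":
            data = trimesh.exchange.stl.export_stl_ascii(tm).encode()
        else:
            data = trimesh.exchange.stl.export_stl(tm)
    else:  # obj is ascii-only
        data = trimesh.exchange.obj.export_obj(tm).encode()
    try:
        path.write_bytes(data)
    except OSError as exc:
        raise MeshIOError(f"cannot write {path}: {exc}") from exc
    return path
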