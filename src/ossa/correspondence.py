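"""Dense correspondence: template selection and nearest-neighbor resampling.

Every training shape is resampled onto the connectivity of a template mesh —
the specimen of median centroid size, remeshed to the uniform 2 mm edge
length — by mapping each template vertex to its nearest neighbor on the
target (nearest target vertex by default, or the nearest point on the target
surface). All shapes must already be expressed in their anatomical frames;
no non-rigid warping is applied, so the per-shape mean correspondence
distance is retained as a quality-control metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import closest_point_on_mesh
from .mesh import TriangleMesh
from .remesh import remesh_uniform

__all__ = [
    "CorrespondedSet",
    "select_template",
    "register_nearest_neighbor",
    "build_corresponded_set",
]


@dataclass
class CorrespondedSet:
    """K shapes sharing one connectivity: the PCA input.

    template : the reference mesh whose faces all shapes adopt
    shapes : (K, P, 3) vertex arrays
    ids : K shape labels
    mean_nn_distance : per-shape mean template-to-target distance, mm (QC)
    """

    template: TriangleMesh
    shapes: np.ndarray
    ids: List[str]
    mean_nn_distance: Optional[np.ndarray] = None

    def __post_init__(self):
        self.shapes = np.asarray(self.shapes, dtype=np.float64)
        if self.shapes.ndim != 3 or self.shapes.shape[2] != 3:
            raise ValueError(f"shapes must be (K, P, 3), got {self.shapes.shape}")
        if self.shapes.shape[1] != self.template.n_vertices:
            raise ValueError(
                f"shapes have {self.shapes.shape[1]} vertices but template has {self.template.n_vertices}"
            )
        if not np.isfinite(self.shapes).all():
            raise ValueError("shape coordinates must be finite")
        if len(self.ids) != len(self.shapes):
            raise ValueError("one id per shape required")

    @property
    def k(self) -> int:
        return len(self.shapes)

    @property
    def p(self) -> int:
        return self.shapes.shape[1]

    def as_mesh(self, index: int) -> TriangleMesh:
        return self.template.with_vertices(self.shapes[index])


def select_template(meshes: Sequence[TriangleMesh]) -> int:
    """Index of the median-centroid-size mesh (lower median for even K).

    Scale dominates shape variation in long-bone populations, so centroid
    size is the natural order statistic for picking a "median" specimen.
    """
    if len(meshes) == 0:
        raise ValueError("cannot select a template from an empty list")
    sizes = np.array([m.centroid_size() for m in meshes])
    order = np.argsort(sizes, kind="stable")
    return int(order[(len(meshes) - 1) // 2])


def register_nearest_neighbor(
    template: TriangleMesh,
    target: TriangleMesh,
    mode: str = "vertex",
) -> np.ndarray:
    """Resample the target onto the template connectivity.

    mode="vertex": output vertex i is the nearest *target vertex* to template
    vertex i (ties broken toward the lowest target index). mode="surface":
    the nearest point on the target surface. Both require the meshes to share
    an anatomical frame.
    """
    if target.n_vertices == 0:
        raise ValueError("target mesh is empty")
    if mode == "vertex":
        tree = cKDTree(target.vertices)
        if target.n_vertices == 1:
            return np.repeat(target.vertices, template.n_vertices, axis=0)
        d, nn = tree.query(template.vertices, k=2)
        tie = np.isclose(d[:, 0], d[:, 1], rtol=1e-12, atol=1e-12)
        idx = nn[:, 0].copy()
        idx[tie] = nn[tie].min(axis=1)  # documented tie-break: lowest target index
        return target.vertices[idx].copy()
    if mode == "surface":
        closest, _, _ = closest_point_on_mesh(target.vertices, target.faces, template.vertices)
        return closest
    raise ValueError(f"mode must be 'vertex' or 'surface', got {mode!r}")


def build_corresponded_set(
    meshes: Sequence[TriangleMesh],
    template_index: Optional[int] = None,
    mode: str = "vertex",
    ids: Optional[Sequence[str]] = None,
    remesh_template: bool = True,
    target_edge: float = 2.0,
) -> CorrespondedSet:
    """Unify vertex count and connectivity across a training set.

    The template (auto-selected as the median specimen unless given) is
    remeshed to the uniform target edge length, then every training mesh —
    including the template's own source — is resampled onto it by nearest
    neighbor. Requires every mesh to carry the anatomical-alignment flag.
    """
    if len(meshes) == 0:
        raise ValueError("empty training set")
    for m in meshes:
        if not m.aligned:
            raise ValueError(
                f"mesh {m.name!r} is not aligned to an anatomical frame; correspondence requires alignment"
            )
    if ids is None:
        ids = [m.name or f"shape_{i}" for i, m in enumerate(meshes)]
    if template_index is None:
        template_index = select_template(meshes)
    template = meshes[template_index]
    if remesh_template:
        template = remesh_uniform(template, target_edge)
    shapes = np.empty((len(meshes), template.n_vertices, 3))
    dists = np.empty(len(meshes))
    for i, mesh in enumerate(meshes):
        try:
            shapes[i] = register_nearest_neighbor(template, mesh, mode=mode)
        except Exception as exc:
            raise RuntimeError(f"registration failed for shape {ids[i]!r}: {exc}") from exc
        dists[i] = float(np.linalg.norm(shapes[i] - template.vertices, axis=1).mean())
    return CorrespondedSet(template=template, shapes=shapes, ids=list(ids), mean_nn_distance=dists)
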