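"""Anatomical geometry: sphere fits, coordinate frames, alignment, cuts, ICP.

The femoral frame follows the joint-kinematics convention: origin at the
point equidistant from the two condyle-sphere centers, Y along the anatomical
(shaft) axis with positive direction proximal, Z latero-medial with positive
toward the medial condyle (re-orthogonalized against Y, which is kept exact),
and X = Y x Z completing a right-handed triad. Because Z always points
medial, the anatomical X direction (cranial/caudal) flips between left and
right bones; frames are right-handed either way.

Partial-bone models: the distal (condyle) and proximal (head) femur segments
are cut to twice the reference-sphere diameter measured along Y from the
respective bone end, and the proximal tibia is cut at the most distal point
of the tibial tuberosity (a manual landmark).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .geometry import kabsch
from .mesh import TriangleMesh

__all__ = [
    "Sphere",
    "AnatomicalFrame",
    "LandmarkSet",
    "DegenerateFitError",
    "fit_sphere",
    "estimate_anatomical_axis",
    "build_femoral_frame",
    "align_to_frame",
    "cut_partial_femur",
    "cut_partial_tibia",
    "rigid_align_regions",
]


class DegenerateFitError(ValueError):
    """Raised when geometric fitting input is rank-deficient (coplanar /
    collinear points, coincident centers, near-parallel axes)."""


@dataclass
class Sphere:
    center: np.ndarray
    radius: float
    rms: Optional[float] = None  # fit residual, mm; None for constructed spheres

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)
        if not np.isfinite(self.center).all():
            raise ValueError("sphere center must be finite")
        if not self.radius > 0:
            raise ValueError(f"sphere radius must be positive, got {self.radius}")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass
class AnatomicalFrame:
    """Origin plus a right-handed orthonormal axis triad (rows X, Y, Z)."""

    origin: np.ndarray
    axes: np.ndarray  # 3x3, rows are X, Y, Z unit vectors

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.axes = np.asarray(self.axes, dtype=np.float64).reshape(3, 3)
        G = self.axes @ self.axes.T
        if np.abs(G - np.eye(3)).max() > 1e-9:
            raise ValueError("frame axes must be orthonormal within 1e-9")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("frame must be right-handed (det +1)")

    @property
    def x(self) -> np.ndarray:
        return self.axes[0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[2]

    @classmethod
    def identity(cls) -> "AnatomicalFrame":
        return cls(np.zeros(3), np.eye(3))

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """World -> frame coordinates (rigid)."""
        return (np.asarray(points) - self.origin) @ self.axes.T

    def to_world(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.axes + self.origin


_PATCH_KEYS = ("condyle_medial_patch", "condyle_lateral_patch", "head_patch")
_POINT_KEYS = ("tuberosity_distal_point", "shaft_proximal_point", "shaft_distal_point", "proximal_point")


@dataclass
class LandmarkSet:
    """Named landmarks: vertex-index patches and explicit 3-D points (mm),
    in the same space as the mesh they annotate."""

    patches: dict = field(default_factory=dict)  # name -> int index array
    points: dict = field(default_factory=dict)  # name -> (3,) float array

    def __post_init__(self):
        self.patches = {k: np.asarray(v, dtype=np.int64).ravel() for k, v in self.patches.items()}
        self.points = {k: np.asarray(v, dtype=np.float64).reshape(3) for k, v in self.points.items()}

    def validate_for(self, mesh: TriangleMesh, required: tuple = ()) -> None:
        for name, idx in self.patches.items():
            if len(idx) and (idx.min() < 0 or idx.max() >= mesh.n_vertices):
                raise ValueError(f"landmark patch {name!r} references vertex out of range")
        for name in required:
            if name not in self.patches and name not in self.points:
                raise ValueError(f"required landmark {name!r} missing")

    def patch_points(self, mesh: TriangleMesh, name: str) -> np.ndarray:
        return mesh.vertices[self.patches[name]]

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        patches, points = {}, {}
        for k, v in d.items():
            arr = np.asarray(v)
            if arr.ndim == 1 and arr.shape == (3,) and not k.endswith("_patch"):
                points[k] = arr
            else:
                patches[k] = arr
        return cls(patches, points)

    def to_dict(self) -> dict:
        out = {k: v.tolist() for k, v in self.patches.items()}
        out.update({k: v.tolist() for k, v in self.points.items()})
        return out


def fit_sphere(points: np.ndarray, refine: bool = False) -> Sphere:
    """Least-squares sphere through >= 4 non-coplanar points.

    The algebraic (linearized) normal-equation solve is exact on noiseless
    data; ``refine=True`` follows it with a geometric Levenberg-Marquardt
    polish minimizing radial residuals.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(pts) < 4:
        raise DegenerateFitError(f"sphere fit needs >= 4 points, got {len(pts)}")
    # |x|^2 = 2 c.x + (r^2 - |c|^2): linear in (c, r^2 - |c|^2)
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise DegenerateFitError("points are coplanar/collinear; sphere fit is rank-deficient")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateFitError("degenerate sphere fit (non-positive squared radius)")
    radius = float(np.sqrt(r2))
    if refine:
        def resid(p):
            return np.linalg.norm(pts - p[:3], axis=1) - p[3]

        res = least_squares(resid, np.r_[center, radius], method="lm")
        center, radius = res.x[:3], float(res.x[3])
    rms = float(np.sqrt(np.mean((np.linalg.norm(pts - center, axis=1) - radius) ** 2)))
    return Sphere(center, radius, rms=rms)


def estimate_anatomical_axis(
    mesh: TriangleMesh,
    shaft_fraction: tuple = (0.25, 0.75),
    n_sections: int = 12,
) -> np.ndarray:
    """Anatomical (shaft) axis as the total-least-squares line through
    cross-section centroids.

    The dominant elongation direction (leading PCA axis of the vertices)
    defines the sectioning direction; centroids of ``n_sections`` slabs
    within ``shaft_fraction`` of the bone's extent are fit with a TLS line.
    Sign convention: the component of largest magnitude is made positive
    (callers flip to enforce "positive = proximal" when the proximal end is
    known).
    """
    lo, hi = shaft_fraction
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"shaft_fraction must be an increasing pair in [0, 1], got {shaft_fraction}")
    v = mesh.vertices
    centered = v - v.mean(axis=0)
    _, svals, Vt = np.linalg.svd(centered, full_matrices=False)
    if svals[0] < 2.0 * svals[1]:
        raise DegenerateFitError(
            "mesh has no dominant elongation direction; cannot estimate a shaft axis"
        )
    t = centered @ Vt[0]
    tmin, tmax = t.min(), t.max()
    edges = np.linspace(tmin + lo * (tmax - tmin), tmin + hi * (tmax - tmin), n_sections + 1)
    centroids = []
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (t >= a) & (t < b)
        if sel.sum() >= 3:
            centroids.append(v[sel].mean(axis=0))
    if len(centroids) < 3:
        raise DegenerateFitError("fewer than 3 nonempty cross-sections in the shaft region")
    C = np.asarray(centroids)
    _, _, Vt2 = np.linalg.svd(C - C.mean(axis=0), full_matrices=False)
    axis = Vt2[0]
    axis = axis / np.linalg.norm(axis)
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return axis


def build_femoral_frame(
    condyle_med: Sphere,
    condyle_lat: Sphere,
    anatomical_axis: np.ndarray,
    side: str,
) -> AnatomicalFrame:
    """Construct the anatomical frame from the condyle spheres and shaft axis.

    Y is the anatomical axis kept exact; Z is the medial-pointing
    inter-condylar direction orthogonalized against Y; X = Y x Z. ``side``
    is recorded for interpretation only — the medial direction comes from
    which sphere is labelled medial.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    y = np.asarray(anatomical_axis, dtype=np.float64)
    ny = np.linalg.norm(y)
    if ny == 0:
        raise ValueError("anatomical axis must be nonzero")
    y = y / ny
    d = condyle_med.center - condyle_lat.center
    nd = np.linalg.norm(d)
    if nd < 1e-12:
        raise DegenerateFitError("condyle sphere centers coincide")
    d = d / nd
    angle = np.degrees(np.arccos(np.clip(np.abs(y @ d), -1.0, 1.0)))
    if angle < 5.0:
        raise DegenerateFitError(
            f"anatomical axis within 5 deg of the inter-condylar line ({angle:.2f} deg)"
        )
    z = d - (d @ y) * y
    nz = np.linalg.norm(z)
    if nz < 1e-12:
        raise DegenerateFitError("axis parallel to inter-condylar direction")
    z = z / nz
    x = np.cross(y, z)
    origin = 0.5 * (condyle_med.center + condyle_lat.center)
    return AnatomicalFrame(origin, np.vstack([x, y, z]))


def align_to_frame(mesh: TriangleMesh, frame: AnatomicalFrame) -> TriangleMesh:
    """Express the mesh in the anatomical frame (rigid; distances exact)."""
    out = mesh.with_vertices(frame.to_local(mesh.vertices))
    out.aligned = True
    return out


def _require_aligned(mesh: TriangleMesh, op: str) -> None:
    if not mesh.aligned:
        raise ValueError(f"{op} requires a mesh aligned to an anatomical frame (aligned flag unset)")


def _keep_vertices(mesh: TriangleMesh, keep: np.ndarray) -> TriangleMesh:
    """Sub-mesh of faces whose three vertices are all kept; open boundary
    left as-is."""
    idx = np.where(keep)[0]
    if len(idx) == 0:
        raise ValueError("cut removes every vertex")
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[idx] = np.arange(len(idx))
    fkeep = keep[mesh.faces].all(axis=1)
    faces = remap[mesh.faces[fkeep]]
    return TriangleMesh(mesh.vertices[idx], faces, name=mesh.name, side=mesh.side, aligned=mesh.aligned)


def cut_partial_femur(mesh: TriangleMesh, region: str, reference_sphere: Sphere) -> TriangleMesh:
    """Cut the distal (condyles) or proximal (head) femur segment.

    The retained length along Y is twice the reference sphere's diameter
    (condyle sphere for the distal cut, head sphere for the proximal cut),
    measured from the corresponding bone end; the cut plane is perpendicular
    to Y. If the cut length reaches the whole bone, the full mesh is
    returned with a warning.
    """
    _require_aligned(mesh, "cut_partial_femur")
    if region not in ("distal", "proximal"):
        raise ValueError(f"region must be 'distal' or 'proximal', got {region!r}")
    length = 2.0 * reference_sphere.diameter
    y = mesh.vertices[:, 1]
    span = y.max() - y.min()
    if length >= span:
        warnings.warn(
            f"partial-femur cut length {length:.1f} mm exceeds bone length {span:.1f} mm; "
            "returning the whole mesh",
            stacklevel=2,
        )
        return mesh
    keep = y <= y.min() + length if region == "distal" else y >= y.max() - length
    return _keep_vertices(mesh, keep)


def cut_partial_tibia(mesh: TriangleMesh, tuberosity_distal_point: np.ndarray) -> TriangleMesh:
    """Cut the proximal tibia at the most distal point of the tibial
    tuberosity (manual landmark); retains vertices with Y >= landmark Y."""
    _require_aligned(mesh, "cut_partial_tibia")
    y_cut = float(np.asarray(tuberosity_distal_point, dtype=np.float64).reshape(3)[1])
    y = mesh.vertices[:, 1]
    if y_cut <= y.min():
        return mesh
    if y_cut > y.max():
        raise ValueError(
            f"tuberosity landmark Y={y_cut:.1f} lies above the proximal end {y.max():.1f}; empty cut"
        )
    return _keep_vertices(mesh, y >= y_cut)


def rigid_align_regions(
    source: TriangleMesh,
    target: TriangleMesh,
    region_indices: np.ndarray,
    max_iterations: int = 50,
    tol: float = 1e-8,
):
    """Rigid ICP of a source sub-region onto a target mesh.

    Iterates closest-point matching (source region vertices to nearest
    target vertices) with a Kabsch solve, starting at identity; no scaling.

    Returns
    -------
    (R, t) : rotation and translation mapping source -> target
    transformed : the whole source mesh under (R, t)
    rms : final region RMS distance, mm
    """
    region_indices = np.asarray(region_indices, dtype=np.int64).ravel()
    if len(region_indices) < 3:
        raise DegenerateFitError("region needs >= 3 points")
    pts = source.vertices[region_indices]
    rank = np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9 * max(1.0, np.abs(pts).max()))
    if rank < 2:
        raise DegenerateFitError("region points are collinear")
    tree = cKDTree(target.vertices)
    R = np.eye(3)
    t = np.zeros(3)
    prev_rms = np.inf
    converged = False
    for _ in range(max_iterations):
        moved = pts @ R.T + t
        dist, nn = tree.query(moved)
        matched = target.vertices[nn]
        R, t = kabsch(pts, matched)
        rms = float(np.sqrt((dist**2).mean()))
        if abs(prev_rms - rms) < tol:
            converged = True
            break
        prev_rms = rms
    if not converged:
        warnings.warn(
            f"regional ICP did not converge in {max_iterations} iterations (rms {rms:.4g} mm); "
            "returning best transform",
            stacklevel=2,
        )
    transformed = source.with_vertices(source.vertices @ R.T + t)
    return (R, t), transformed, rms
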