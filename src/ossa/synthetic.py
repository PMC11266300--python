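"""Synthetic bone populations with known latent structure.

Real canine CT data are access-restricted, so every pipeline stage is
exercised on generated femur/tibia/patella-like surfaces whose ground-truth
factors of variation are recorded per specimen. A canonical bone is built as
the smooth union of implicit primitives (capsule shaft, condylar spheres,
head sphere, trochanter bump) extracted by marching cubes, and each specimen
is a smooth warp of that canonical mesh:

* global scale ``exp(N(0, scale_sd))`` (log-scale SD, the dominant factor),
* varus/valgus: frontal-plane bend of the distal shaft (degrees),
* procurvation: sagittal-plane bow (degrees),
* torsion: axial twist of the distal half against the proximal (degrees),
* condyle width: fractional widening of the distal end.

Factors are applied in the fixed order width -> scale -> varus ->
procurvation -> torsion so the latent records are interpretable. Warps are
smooth bijections, so watertightness and manifoldness of the canonical mesh
are preserved exactly. The generator also emits per-specimen landmark files
(condyle/head vertex patches, proximal reference point) consistent with the
geometry, and can voxelize meshes into CT-like volumes (inside 1000,
outside 0, so a 350 threshold separates bone from background).

What this emulates — and what it does not: populations share the canonical
connectivity before correspondence, surfaces are smooth and artifact-free,
and the latent factors are exactly low-rank. Real CT bones add segmentation
noise, cortical detail and breed-specific local shape; passing here
validates the pipeline's mechanics and its factor recovery, not clinical
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from skimage import measure

from .anatomy import LandmarkSet
from .geometry import points_in_mesh
from .mesh import TriangleMesh
from .volume import VoxelVolume

__all__ = [
    "BoneDimensions",
    "BonePopulationSpec",
    "LatentRecord",
    "generate_bone_population",
    "voxelize_mesh",
    "make_group_fixture",
    "GROUP_FIXTURES",
]


# ---------------------------------------------------------------------------
# specs and records
# ---------------------------------------------------------------------------


@dataclass
class BoneDimensions:
    """Canonical femur-like dimensions, mm (left-side pose: +Y proximal,
    +Z medial, condyles at the distal end)."""

    shaft_length: float = 120.0
    shaft_radius: float = 8.0
    condyle_radius: float = 10.0
    condyle_halfwidth: float = 9.0
    head_radius: float = 11.0

    def __post_init__(self):
        for name in ("shaft_length", "shaft_radius", "condyle_radius", "condyle_halfwidth", "head_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BonePopulationSpec:
    """Study-condition parameters for one generated population.

    Defaults are the reference conditions used throughout the test suite:
    log-scale SD 0.1 dominating, 2 degrees of varus/valgus, smaller
    procurvation/torsion, and a few-percent condyle-width factor.
    """

    n: int = 30
    scale_sd: float = 0.1
    varus_sd: float = 2.0
    procurv_sd: float = 1.0
    torsion_sd: float = 1.0
    condyle_width_sd: float = 0.02
    seed: int = 0
    bone: str = "femur"  # femur | tibia | patella
    side: str = "left"
    dimensions: BoneDimensions = field(default_factory=BoneDimensions)
    resolution: float = 1.6  # marching-cubes grid pitch, mm

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"population needs n >= 2, got {self.n}")
        for name in ("scale_sd", "varus_sd", "procurv_sd", "torsion_sd", "condyle_width_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.bone not in ("femur", "tibia", "patella"):
            raise ValueError(f"unknown bone {self.bone!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {self.side!r}")


@dataclass
class LatentRecord:
    """Ground-truth factors realized for one specimen."""

    id: str
    scale: float  # log-scale
    varus_deg: float
    procurv_deg: float
    torsion_deg: float
    condyle_width: float


# ---------------------------------------------------------------------------
# implicit canonical bones
# ---------------------------------------------------------------------------


def _d_sphere(p, center, r):
    return np.linalg.norm(p - center, axis=-1) - r


def _d_capsule(p, a, b, r):
    a = np.asarray(a, dtype=float)
    ab = np.asarray(b, dtype=float) - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(p - (a + t[:, None] * ab), axis=-1) - r


def _d_ellipsoid(p, center, radii):
    # scaled-space approximation, adequate for iso-surfacing
    q = (p - center) / np.asarray(radii, dtype=float)
    return (np.linalg.norm(q, axis=-1) - 1.0) * min(radii)


def _smooth_min(d1, d2, k=4.0):
    h = np.clip(0.5 + 0.5 * (d2 - d1) / k, 0.0, 1.0)
    return d2 + (d1 - d2) * h - k * h * (1.0 - h)


def _femur_primitives(dim: BoneDimensions):
    """Femur-like implicit primitives in the canonical left-side pose.

    Prominences are deliberately gentle and broadly blended: real cortical
    surfaces flare smoothly into the epiphyses, and exaggerated bulges would
    be an artifact, not anatomy.
    """
    L = dim.shaft_length
    r = dim.shaft_radius
    head_center = np.array([0.0, L + 0.35 * dim.head_radius, 4.0])
    troch_center = np.array([0.0, L, -0.8 * dim.condyle_halfwidth])
    prims = {
        "shaft": ("capsule", np.array([0.0, 2.0, 0.0]), np.array([0.0, L - 2.0, 0.0]), r),
        "neck": ("capsule", np.array([0.0, L - 10.0, 0.0]), head_center, 0.9 * r),
        "head": ("sphere", head_center, dim.head_radius),
        "trochanter": ("sphere", troch_center, 0.45 * dim.head_radius),
        "condyle_medial": ("sphere", np.array([0.5, 0.0, dim.condyle_halfwidth]), dim.condyle_radius),
        "condyle_lateral": ("sphere", np.array([0.5, 0.0, -dim.condyle_halfwidth]), dim.condyle_radius),
        "distal_flare": ("capsule", np.array([0.0, 0.3 * L, 0.0]), np.array([0.0, 0.0, 0.0]), 1.05 * r),
    }
    return prims


def _tibia_primitives(dim: BoneDimensions):
    L = dim.shaft_length
    plateau_center = np.array([0.0, L, 0.0])
    tuber_center = np.array([1.3 * dim.shaft_radius, L - 2.2 * dim.condyle_radius, 0.0])
    prims = {
        "shaft": ("capsule", np.array([0.0, 0.0, 0.0]), np.array([0.0, L, 0.0]), dim.shaft_radius),
        "plateau": (
            "ellipsoid",
            plateau_center,
            (1.3 * dim.condyle_radius, 0.55 * dim.condyle_radius, 1.6 * dim.condyle_radius),
        ),
        "tuberosity": ("sphere", tuber_center, 0.55 * dim.condyle_radius),
        "malleolus": ("sphere", np.array([0.0, -2.0, 0.0]), 0.9 * dim.shaft_radius),
    }
    return prims


def _patella_primitives(dim: BoneDimensions):
    r = dim.condyle_radius
    return {
        "body": ("ellipsoid", np.zeros(3), (0.55 * r, 1.1 * r, 0.7 * r)),
        "apex": ("sphere", np.array([0.0, -1.0 * r, 0.0]), 0.35 * r),
        # mild cranial ridge; breaks the x symmetry so principal-axis
        # alignment orients consistently across specimens
        "ridge": ("sphere", np.array([0.45 * r, 0.2 * r, 0.0]), 0.4 * r),
    }


def _eval_primitive(kind_args, p):
    kind = kind_args[0]
    if kind == "sphere":
        return _d_sphere(p, kind_args[1], kind_args[2])
    if kind == "capsule":
        return _d_capsule(p, kind_args[1], kind_args[2], kind_args[3])
    return _d_ellipsoid(p, kind_args[1], kind_args[2])


def _canonical_mesh(prims: dict, resolution: float, smooth_k: float = 5.0) -> Tuple[TriangleMesh, np.ndarray]:
    """Marching-cubes extraction of the smooth union of primitives.

    Returns the mesh and, per vertex, the index of the primitive whose
    surface it lies closest to (used to define landmark patches).
    """
    # bounding box over primitive supports
    pts = []
    for kind_args in prims.values():
        kind = kind_args[0]
        if kind == "sphere":
            c, r = kind_args[1], kind_args[2]
            pts += [c - r, c + r]
        elif kind == "capsule":
            a, b, r = kind_args[1], kind_args[2], kind_args[3]
            pts += [a - r, a + r, b - r, b + r]
        else:
            c, radii = kind_args[1], np.asarray(kind_args[2])
            pts += [c - radii, c + radii]
    pts = np.asarray(pts)
    lo = pts.min(axis=0) - 3.0 * resolution
    hi = pts.max(axis=0) + 3.0 * resolution
    axes = [np.arange(l, h + resolution, resolution) for l, h in zip(lo, hi)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    grid_pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    dists = np.stack([_eval_primitive(ka, grid_pts) for ka in prims.values()])
    f = dists[0]
    for d in dists[1:]:
        f = _smooth_min(f, d, k=smooth_k)
    f = f.reshape(X.shape)

    verts, faces, _, _ = measure.marching_cubes(f, level=0.0, spacing=(resolution,) * 3)
    verts = verts + lo
    mesh = TriangleMesh(verts, faces)
    if mesh.enclosed_volume() < 0:
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1])
    vd = np.stack([np.abs(_eval_primitive(ka, mesh.vertices)) for ka in prims.values()])
    nearest_prim = vd.argmin(axis=0)
    return mesh, nearest_prim


def _landmarks_for_femur(mesh, nearest_prim, prims) -> LandmarkSet:
    names = list(prims)
    vd = {n: np.abs(_eval_primitive(prims[n], mesh.vertices)) for n in names}

    def patch(primname, tol=1.0):
        i = names.index(primname)
        on = (nearest_prim == i) & (vd[primname] < tol)
        return np.where(on)[0]

    L_axis_hi = prims["shaft"][2]  # proximal shaft endpoint
    return LandmarkSet(
        patches={
            "condyle_medial_patch": patch("condyle_medial"),
            "condyle_lateral_patch": patch("condyle_lateral"),
            "head_patch": patch("head"),
        },
        points={
            "proximal_point": np.asarray(prims["head"][1], dtype=float),
            "shaft_proximal_point": np.asarray(L_axis_hi, dtype=float),
            "shaft_distal_point": np.asarray(prims["shaft"][1], dtype=float),
        },
    )


def _landmarks_for_tibia(mesh, nearest_prim, prims) -> LandmarkSet:
    names = list(prims)
    i_tub = names.index("tuberosity")
    tub_verts = mesh.vertices[nearest_prim == i_tub]
    if len(tub_verts) == 0:
        tub_point = np.asarray(prims["tuberosity"][1], dtype=float)
    else:
        tub_point = tub_verts[np.argmin(tub_verts[:, 1])]
    return LandmarkSet(
        points={
            "tuberosity_distal_point": tub_point,
            "proximal_point": np.asarray(prims["plateau"][1], dtype=float),
            "shaft_proximal_point": np.asarray(prims["shaft"][2], dtype=float),
            "shaft_distal_point": np.asarray(prims["shaft"][1], dtype=float),
        }
    )


# ---------------------------------------------------------------------------
# smooth latent warps
# ---------------------------------------------------------------------------


def _smoothstep(t):
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


_AXIS_PLANES = {"x": (1, 2), "y": (2, 0), "z": (0, 1)}


def _graded_rotation(points, axis: str, pivot, angle_rad, y_full, y_zero):
    """Rotate points about a coordinate ``axis`` through ``pivot`` with a
    per-point angle ramping smoothly from full at y <= y_full to zero at
    y >= y_zero (a smooth bend/twist)."""
    w = _smoothstep((y_zero - points[:, 1]) / (y_zero - y_full))
    theta = w * angle_rad
    i, j = _AXIS_PLANES[axis]
    out = points.copy()
    u = points[:, i] - pivot[i]
    v = points[:, j] - pivot[j]
    c, s = np.cos(theta), np.sin(theta)
    out[:, i] = c * u - s * v + pivot[i]
    out[:, j] = s * u + c * v + pivot[j]
    return out


def _warp_specimen(verts: np.ndarray, rec: LatentRecord, dim: BoneDimensions) -> np.ndarray:
    """Apply latent factors in the fixed order width -> scale -> varus ->
    procurvation -> torsion. The same map applies to meshes and to landmark
    points."""
    L = dim.shaft_length
    v = verts.copy()
    # condyle width: widen z in the distal third
    w = _smoothstep((0.4 * L - v[:, 1]) / (0.4 * L))
    v[:, 2] *= 1.0 + rec.condyle_width * w
    # global scale
    v *= np.exp(rec.scale)
    Ls = L * np.exp(rec.scale)
    pivot = np.array([0.0, 0.55 * Ls, 0.0])
    # varus/valgus: frontal-plane bend of the distal shaft (about X)
    v = _graded_rotation(v, "x", pivot, np.deg2rad(rec.varus_deg), 0.15 * Ls, 0.55 * Ls)
    # procurvation: sagittal bow (about Z)
    v = _graded_rotation(v, "z", pivot, np.deg2rad(rec.procurv_deg), 0.15 * Ls, 0.55 * Ls)
    # torsion: axial twist of the distal half (about Y)
    v = _graded_rotation(v, "y", pivot, np.deg2rad(rec.torsion_deg), 0.15 * Ls, 0.55 * Ls)
    return v


# ---------------------------------------------------------------------------
# population generation
# ---------------------------------------------------------------------------

_PRIMS = {"femur": _femur_primitives, "tibia": _tibia_primitives, "patella": _patella_primitives}


def generate_bone_population(spec: BonePopulationSpec):
    """Generate ``spec.n`` bone meshes plus latent records and landmarks.

    Deterministic for a fixed spec (seeded generator; no global RNG state).

    Returns
    -------
    meshes : list of TriangleMesh (watertight, shared connectivity)
    records : list of LatentRecord
    landmarks : list of LandmarkSet, one per specimen, in specimen space
    """
    rng = np.random.default_rng(spec.seed)
    prims = _PRIMS[spec.bone](spec.dimensions)
    canonical, nearest_prim = _canonical_mesh(prims, spec.resolution)
    if spec.bone == "femur":
        base_lm = _landmarks_for_femur(canonical, nearest_prim, prims)
    elif spec.bone == "tibia":
        base_lm = _landmarks_for_tibia(canonical, nearest_prim, prims)
    else:
        base_lm = LandmarkSet(points={"proximal_point": np.array([0.0, 2.0 * spec.dimensions.condyle_radius, 0.0])})

    mirror = spec.side == "right"
    verts0 = canonical.vertices.copy()
    faces0 = canonical.faces.copy()
    if mirror:
        verts0 = verts0 * np.array([1.0, 1.0, -1.0])
        faces0 = faces0[:, ::-1]

    n = spec.n
    scales = rng.normal(0.0, spec.scale_sd, n)
    varus = rng.normal(0.0, spec.varus_sd, n)
    procurv = rng.normal(0.0, spec.procurv_sd, n)
    torsion = rng.normal(0.0, spec.torsion_sd, n)
    widths = rng.normal(0.0, spec.condyle_width_sd, n)

    meshes, records, landmarks = [], [], []
    for i in range(n):
        rec = LatentRecord(
            id=f"{spec.bone}_{spec.side}_{i:03d}",
            scale=float(scales[i]),
            varus_deg=float(varus[i]),
            procurv_deg=float(procurv[i]),
            torsion_deg=float(torsion[i]),
            condyle_width=float(widths[i]),
        )
        v = _warp_specimen(verts0, rec, spec.dimensions)
        mesh = TriangleMesh(v, faces0, name=rec.id, side=spec.side)
        pts = {
            k: _warp_specimen(p[None, :], rec, spec.dimensions)[0]
            for k, p in base_lm.points.items()
        }
        lm = LandmarkSet(patches=dict(base_lm.patches), points=pts)
        meshes.append(mesh)
        records.append(rec)
        landmarks.append(lm)
    return meshes, records, landmarks


def voxelize_mesh(mesh: TriangleMesh, spacing: float = 1.0, pad: int = 3) -> VoxelVolume:
    """Voxelize a closed mesh into a CT-like volume (inside 1000, outside 0).

    Voxel centers are classified by ray-crossing parity; spacing is
    isotropic (mm) and the grid is padded by ``pad`` voxels of background.
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    if pad < 1:
        raise ValueError("pad must be >= 1 so the surface does not touch the grid boundary")
    lo = mesh.vertices.min(axis=0) - pad * spacing
    hi = mesh.vertices.max(axis=0) + pad * spacing
    axes = [np.arange(l, h + spacing, spacing) for l, h in zip(lo, hi)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    inside = points_in_mesh(mesh.vertices, mesh.faces, centers)
    data = np.where(inside, 1000.0, 0.0).reshape(X.shape)
    return VoxelVolume(data, np.full(3, float(spacing)), lo)


# ---------------------------------------------------------------------------
# named group fixtures (study-composition analogues)
# ---------------------------------------------------------------------------

# weight bands map to base shaft lengths; a fixture convention, not biology
_BAND_DIMS = {
    "small": BoneDimensions(shaft_length=120.0, shaft_radius=7.0, condyle_radius=9.0, condyle_halfwidth=8.0, head_radius=10.0),
    "medium": BoneDimensions(shaft_length=160.0, shaft_radius=8.0, condyle_radius=10.0, condyle_halfwidth=9.0, head_radius=11.0),
    "large": BoneDimensions(shaft_length=200.0, shaft_radius=9.5, condyle_radius=11.5, condyle_halfwidth=10.5, head_radius=12.5),
    "chondro": BoneDimensions(shaft_length=105.0, shaft_radius=8.5, condyle_radius=10.0, condyle_halfwidth=9.5, head_radius=10.5),
}

# name -> (bone, [(band, n), ...]) matching the study's group sizes
GROUP_FIXTURES = {
    "group1_whole_femur": ("femur", [("small", 21), ("medium", 18), ("large", 22)]),
    "group2_0_10kg": ("femur", [("small", 21)]),
    "group3_10_25kg": ("femur", [("medium", 18)]),
    "group4_over_25kg": ("femur", [("large", 22)]),
    "group5_chondrodystrophic": ("femur", [("chondro", 18)]),
    "group6_retrievers": ("femur", [("large", 13)]),
    "femur_condyles": ("femur", [("small", 21), ("medium", 18), ("large", 22)]),
    "femoral_head": ("femur", [("small", 21), ("medium", 18), ("large", 22)]),
    "tibia": ("tibia", [("medium", 30)]),
    "tibia_plateau": ("tibia", [("small", 24), ("medium", 24), ("large", 24)]),
    "patella": ("patella", [("small", 28), ("medium", 29), ("large", 28)]),
}


def make_group_fixture(group: str, seed: int = 0, side: str = "left", resolution: float = 1.6):
    """Population emulating one named study group (sizes as in the study's
    composition table: e.g. the 0-10 kg femur group has 21 specimens, the
    >25 kg group 22). Weight bands draw different base dimensions.

    Returns (meshes, records, landmarks) concatenated across bands.
    """
    if group not in GROUP_FIXTURES:
        raise KeyError(f"unknown group {group!r}; known: {sorted(GROUP_FIXTURES)}")
    bone, bands = GROUP_FIXTURES[group]
    meshes, records, landmarks = [], [], []
    for j, (band, n) in enumerate(bands):
        spec = BonePopulationSpec(
            n=n,
            seed=seed * 1009 + j,
            bone=bone,
            side=side,
            dimensions=_BAND_DIMS[band],
            resolution=resolution,
        )
        ms, rs, ls = generate_bone_population(spec)
        for m, r in zip(ms, rs):
            m.name = f"{group}_{band}_{m.name}"
            r.id = m.name
        meshes += ms
        records += rs
        landmarks += ls
    return meshes, records, landmarks
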