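"""Pipeline orchestration: configuration, per-group model building, reports.

One run covers a list of (group, bone, side) populations. For each group the
stages are: anatomical alignment (sphere fits + shaft axis + frame), an
optional partial-bone cut, median-template selection with 2 mm remeshing,
nearest-neighbor correspondence, PCA model building, the variance table and
the mean / ±3 SD meshes for the first five modes. Everything is
deterministic given the configuration and seed, and a structured QC log
(one JSON record per stage per specimen) is written next to the outputs.

Groups can come from explicit file manifests (mesh + landmark paths) or from
the named synthetic fixtures that emulate the study's group sizes.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import List, Literal, Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

from .anatomy import (
    AnatomicalFrame,
    LandmarkSet,
    align_to_frame,
    build_femoral_frame,
    cut_partial_femur,
    cut_partial_tibia,
    estimate_anatomical_axis,
    fit_sphere,
)
from .correspondence import build_corresponded_set
from .mesh import TriangleMesh, read_mesh, write_mesh
from .ssm import ShapeModel, VarianceTable, build_ssm, sample_mode, save_model, variance_table
from .synthetic import GROUP_FIXTURES, make_group_fixture

__all__ = [
    "GroupSpec",
    "SpecimenInput",
    "GroupInput",
    "PipelineConfig",
    "align_bone",
    "run_pipeline",
    "export_variance_table",
]

Bone = Literal["complete_femur", "femur_condyles", "femoral_head", "tibia", "tibia_plateau", "patella"]


class GroupSpec(BaseModel):
    """Declarative group definition (weight band / breed partition)."""

    model_config = ConfigDict(extra="forbid")

    name: str
    bone: Bone
    side: Literal["left", "right"]
    weight_band_kg: Optional[Tuple[float, float]] = None
    breeds: Optional[List[str]] = None


class SpecimenInput(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mesh: str
    landmarks: Optional[str] = None

    @field_validator("mesh", "landmarks")
    @classmethod
    def _must_exist(cls, v):
        if v is not None and not Path(v).is_file():
            raise ValueError(f"referenced path does not exist: {v}")
        return v


class GroupInput(BaseModel):
    """One population: either a file manifest or a named synthetic fixture."""

    model_config = ConfigDict(extra="forbid")

    spec: GroupSpec
    specimens: Optional[List[SpecimenInput]] = None
    synthetic_fixture: Optional[str] = None

    @field_validator("synthetic_fixture")
    @classmethod
    def _known_fixture(cls, v):
        if v is not None and v not in GROUP_FIXTURES:
            raise ValueError(f"unknown synthetic fixture {v!r}")
        return v

    def model_post_init(self, _ctx) -> None:
        if (self.specimens is None) == (self.synthetic_fixture is None):
            raise ValueError("provide exactly one of specimens / synthetic_fixture")


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    groups: List[GroupInput]
    output_dir: str
    threshold: float = 350.0
    kernel_mm: float = 3.0
    target_edge: float = 2.0
    nn_mode: Literal["vertex", "surface"] = "vertex"
    n_modes: int = 5
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))


# ---------------------------------------------------------------------------
# per-bone frame construction
# ---------------------------------------------------------------------------


def _oriented_axis(mesh: TriangleMesh, lm: LandmarkSet, reference: np.ndarray) -> np.ndarray:
    axis = estimate_anatomical_axis(mesh)
    if "proximal_point" in lm.points:
        centroid = mesh.centroid()
        if axis @ (lm.points["proximal_point"] - centroid) < 0:
            axis = -axis
    elif axis @ reference < 0:
        axis = -axis
    return axis


def align_bone(mesh: TriangleMesh, lm: LandmarkSet, bone: str, side: str):
    """Build the bone-appropriate anatomical frame and align the mesh to it.

    Femur-like bones use the condyle-sphere frame. The tibia uses its shaft
    axis, with the tuberosity defining the cranial direction. The patella —
    a sesamoid with no shaft — uses its principal axes. Returns the aligned
    mesh plus a QC dict (sphere radii/residuals where applicable).
    """
    qc: dict = {"bone": bone, "side": side, "name": mesh.name}
    if bone in ("complete_femur", "femur_condyles", "femoral_head"):
        lm.validate_for(mesh, required=("condyle_medial_patch", "condyle_lateral_patch"))
        s_med = fit_sphere(lm.patch_points(mesh, "condyle_medial_patch"))
        s_lat = fit_sphere(lm.patch_points(mesh, "condyle_lateral_patch"))
        axis = _oriented_axis(mesh, lm, np.array([0.0, 1.0, 0.0]))
        frame = build_femoral_frame(s_med, s_lat, axis, side)
        qc.update(
            condyle_radius_med=s_med.radius,
            condyle_radius_lat=s_lat.radius,
            sphere_rms=max(s_med.rms, s_lat.rms),
        )
        return align_to_frame(mesh, frame), qc
    if bone in ("tibia", "tibia_plateau"):
        axis = _oriented_axis(mesh, lm, np.array([0.0, 1.0, 0.0]))
        origin = lm.points.get("proximal_point", mesh.centroid())
        cranial_ref = lm.points.get("tuberosity_distal_point")
        if cranial_ref is None:
            raise ValueError(f"tibia {mesh.name!r}: tuberosity_distal_point landmark required")
        x = cranial_ref - origin
        x = x - (x @ axis) * axis
        nx = np.linalg.norm(x)
        if nx < 1e-9:
            raise ValueError(f"tibia {mesh.name!r}: tuberosity coincides with the shaft axis")
        x = x / nx
        z = np.cross(x, axis)
        frame = AnatomicalFrame(origin, np.vstack([x, axis, z]))
        return align_to_frame(mesh, frame), qc
    # patella: principal axes, longest as Y; axis signs fixed by the
    # third moment so left/right and apex asymmetries orient consistently
    v = mesh.vertices - mesh.centroid()
    _, _, Vt = np.linalg.svd(v, full_matrices=False)
    y, x = Vt[0], Vt[1]
    if np.sum((v @ y) ** 3) < 0:
        y = -y
    if np.sum((v @ x) ** 3) < 0:
        x = -x
    z = np.cross(x, y)
    frame = AnatomicalFrame(mesh.centroid(), np.vstack([x, y, z]))
    return align_to_frame(mesh, frame), qc


def _apply_cut(mesh: TriangleMesh, lm: LandmarkSet, bone: str) -> TriangleMesh:
    if bone == "femur_condyles":
        pts = np.vstack(
            [lm.patch_points(mesh, "condyle_medial_patch"), lm.patch_points(mesh, "condyle_lateral_patch")]
        )
        return cut_partial_femur(mesh, "distal", fit_sphere(pts))
    if bone == "femoral_head":
        lm.validate_for(mesh, required=("head_patch",))
        head = fit_sphere(lm.patch_points(mesh, "head_patch"))
        out = cut_partial_femur(mesh, "proximal", head)
        # re-origin the proximal segment at the head-sphere center: in the
        # condyle-origin frame, heads of different-length bones sit at very
        # different heights, which would wreck cross-size correspondence
        return out.with_vertices(out.vertices - head.center)
    if bone == "tibia_plateau":
        if "tuberosity_distal_point" not in lm.points:
            raise ValueError("tibia plateau cut needs the tuberosity_distal_point landmark")
        return cut_partial_tibia(mesh, lm.points["tuberosity_distal_point"])
    return mesh


def _load_group(group: GroupInput, seed: int, target_edge: float):
    """Materialize (meshes, landmarks) for a group, from files or synthesis."""
    if group.synthetic_fixture is not None:
        meshes, _records, landmarks = make_group_fixture(
            group.synthetic_fixture, seed=seed, side=group.spec.side
        )
        return meshes, landmarks
    meshes, landmarks = [], []
    for spec_in in group.specimens:
        m = read_mesh(spec_in.mesh)
        m.name = Path(spec_in.mesh).stem
        m.side = group.spec.side
        lm = (
            LandmarkSet.from_dict(json.loads(Path(spec_in.landmarks).read_text()))
            if spec_in.landmarks
            else LandmarkSet()
        )
        meshes.append(m)
        landmarks.append(lm)
    return meshes, landmarks


def _landmarks_to_frame(mesh_aligned: TriangleMesh, mesh_world: TriangleMesh, lm: LandmarkSet) -> LandmarkSet:
    """Express landmark points in the aligned frame (patches are indices and
    carry over unchanged)."""
    if not lm.points:
        return lm
    # recover the rigid map world -> aligned from corresponding vertices
    # (exact because alignment is rigid): solve via three reference vertices
    from .geometry import kabsch

    idx = np.linspace(0, mesh_world.n_vertices - 1, 8, dtype=int)
    R, t = kabsch(mesh_world.vertices[idx], mesh_aligned.vertices[idx])
    return LandmarkSet(
        patches=dict(lm.patches),
        points={k: R @ p + t for k, p in lm.points.items()},
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every group through the full modelling chain.

    Returns a summary dict: per group the model directory, variance table,
    exported mode meshes and QC records. Outputs land under
    ``config.output_dir/<group name>/``.
    """
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    summary = {}
    qc_path = out_root / "qc_log.jsonl"
    with qc_path.open("w") as qc_file:
        for group in config.groups:
            name = group.spec.name
            gdir = out_root / name
            gdir.mkdir(parents=True, exist_ok=True)
            meshes, landmarks = _load_group(group, config.seed, config.target_edge)
            if len(meshes) < 2:
                raise ValueError(f"group {name!r}: shape model needs K >= 2 specimens, got {len(meshes)}")
            aligned = []
            for m, lm in zip(meshes, landmarks):
                try:
                    am, qc = align_bone(m, lm, group.spec.bone, group.spec.side)
                    lm_al = _landmarks_to_frame(am, m, lm)
                    am = _apply_cut(am, lm_al, group.spec.bone)
                except Exception as exc:
                    raise RuntimeError(f"group {name!r}, specimen {m.name!r}: {exc}") from exc
                qc["stage"] = "align"
                qc["group"] = name
                qc_file.write(json.dumps(qc) + "\n")
                aligned.append(am)
            cset = build_corresponded_set(aligned, mode=config.nn_mode, target_edge=config.target_edge)
            for sid, d in zip(cset.ids, cset.mean_nn_distance):
                qc_file.write(
                    json.dumps({"stage": "correspond", "group": name, "name": sid, "mean_nn_mm": float(d)}) + "\n"
                )
            model = build_ssm(
                cset,
                metadata={"group": name, "bone": group.spec.bone, "side": group.spec.side},
            )
            vt = variance_table(model, n_modes=config.n_modes)
            save_model(model, gdir / "model")
            export_variance_table([(name, group.spec.side, vt)], gdir / "variance.csv")
            mesh_paths = []
            write_mesh(model.mean_mesh(), gdir / "mean.ply")
            mesh_paths.append(gdir / "mean.ply")
            for mode_i in range(1, min(config.n_modes, model.n_modes) + 1):
                for sd in (-3.0, 3.0):
                    tag = "m" if sd < 0 else "p"
                    p = gdir / f"mode{mode_i}_{tag}3sd.ply"
                    write_mesh(sample_mode(model, mode_i, sd), p)
                    mesh_paths.append(p)
            summary[name] = {
                "model_dir": gdir / "model",
                "variance_csv": gdir / "variance.csv",
                "variance_table": vt,
                "mode_meshes": mesh_paths,
                "n_training": model.n_training,
                "n_points": model.n_points,
                "mean_nn_mm": float(np.mean(cset.mean_nn_distance)),
            }
    return summary


def export_variance_table(tables: List[Tuple[str, str, VarianceTable]], path) -> Path:
    """CSV in the report layout: one row per mode, a paired A/B column set
    per (group, side), 3 significant figures, stable column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n_modes = max((len(t.per_mode) for _, _, t in tables), default=0)
    header = ["Mode"]
    for name, side, _ in tables:
        header += [f"{name}_{side}_A", f"{name}_{side}_B"]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for i in range(n_modes):
            row = [i + 1]
            for _, _, t in tables:
                a, b = t.rounded()
                row += [_fmt(a[i]), _fmt(b[i])] if i < len(a) else ["", ""]
            writer.writerow(row)
    return path


def _fmt(x: float) -> str:
    s = f"{x:.10g}"
    return s
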