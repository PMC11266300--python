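"""The statistical shape model: PCA over corresponded vertex coordinates.

A point distribution model in the Cootes sense: stack each corresponded
shape's P vertices into a 3P-vector, take the arithmetic mean, and
eigen-decompose the sample covariance (1/(K-1) normalization) of the
centered K x 3P data matrix. Because K << 3P, the decomposition is computed
through the thin SVD of the centered data; eigenvalues are squared singular
values over (K-1), in mm^2. A "mode" is the deformation of the mean shape
along one eigenvector, visualized at +/-3 standard deviations
(mean + k * sqrt(lambda_i) * mode_i). No scale normalization or Procrustes
size removal is applied before PCA — size is deliberately retained as a
shape factor, and on long-bone populations it dominates Mode 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .correspondence import CorrespondedSet
from .mesh import TriangleMesh

__all__ = [
    "ShapeModel",
    "VarianceTable",
    "build_ssm",
    "variance_table",
    "sample_mode",
    "project",
    "reconstruct",
    "save_model",
    "load_model",
    "round_sig",
]

_EIG_TOL = 1e-12  # relative cutoff below which an eigenvalue counts as zero


@dataclass
class ShapeModel:
    """Mean vector + orthonormal modes + eigenvalues of a shape population.

    mean_vector : (3P,) mm
    modes : (3P, M) orthonormal columns, M <= K - 1
    eigenvalues : (M,) mm^2, non-increasing
    n_training : K
    template : mesh carrying the shared connectivity
    metadata : free-form (group name, bone, side, ...)
    """

    mean_vector: np.ndarray
    modes: np.ndarray
    eigenvalues: np.ndarray
    n_training: int
    template: TriangleMesh
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mean_vector = np.asarray(self.mean_vector, dtype=np.float64).ravel()
        self.modes = np.asarray(self.modes, dtype=np.float64)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64).ravel()
        if self.modes.shape != (len(self.mean_vector), len(self.eigenvalues)):
            raise ValueError("modes must be (3P, M) matching mean and eigenvalues")
        if (np.diff(self.eigenvalues) > 1e-9 * max(self.eigenvalues.max(initial=0.0), 1.0)).any():
            raise ValueError("eigenvalues must be non-increasing")
        if (self.eigenvalues < -1e-12).any():
            raise ValueError("eigenvalues must be non-negative")
        if self.n_modes:
            G = self.modes.T @ self.modes
            if np.abs(G - np.eye(self.n_modes)).max() > 1e-8:
                raise ValueError("mode columns must be orthonormal within 1e-8")

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def n_points(self) -> int:
        return len(self.mean_vector) // 3

    def mean_mesh(self) -> TriangleMesh:
        return self.template.with_vertices(self.mean_vector.reshape(-1, 3))


@dataclass
class VarianceTable:
    """Per-mode (column A) and cumulative (column B) percentage of total
    variance, the standard compactness summary of a shape model."""

    per_mode: np.ndarray  # A, unrounded percents
    cumulative: np.ndarray  # B, unrounded percents

    def __post_init__(self):
        self.per_mode = np.asarray(self.per_mode, dtype=np.float64)
        self.cumulative = np.asarray(self.cumulative, dtype=np.float64)
        if self.per_mode.shape != self.cumulative.shape:
            raise ValueError("A and B columns must have equal length")
        if (self.per_mode < 0).any():
            raise ValueError("per-mode percentages must be non-negative")
        if (np.diff(self.cumulative) < -1e-9).any():
            raise ValueError("cumulative column must be non-decreasing")

    def rounded(self, sig: int = 3):
        """Columns rounded to ``sig`` significant figures (report precision)."""
        return round_sig(self.per_mode, sig), round_sig(self.cumulative, sig)

    def to_rows(self, sig: int = 3):
        a, b = self.rounded(sig)
        return [(i + 1, float(ai), float(bi)) for i, (ai, bi) in enumerate(zip(a, b))]


def round_sig(x, sig: int = 3):
    """Round to ``sig`` significant figures, elementwise."""
    x = np.asarray(x, dtype=np.float64)
    out = np.zeros_like(x)
    nz = x != 0
    mag = np.floor(np.log10(np.abs(x[nz])))
    out[nz] = np.round(x[nz] * 10.0 ** (sig - 1 - mag)) * 10.0 ** (mag - (sig - 1))
    return out


def _fix_mode_signs(modes: np.ndarray) -> np.ndarray:
    """Deterministic sign: each mode's largest-magnitude component positive."""
    idx = np.abs(modes).argmax(axis=0)
    signs = np.sign(modes[idx, np.arange(modes.shape[1])])
    signs[signs == 0] = 1.0
    return modes * signs


def build_ssm(cset: CorrespondedSet, metadata: Optional[dict] = None) -> ShapeModel:
    """PCA of a corresponded set via thin SVD of the centered data matrix.

    Keeps the K-1 leading modes (zero eigenvalues included so degenerate
    populations still produce a valid, if empty-spectrum, model).
    """
    if cset.k < 2:
        raise ValueError(f"shape model needs >= 2 training shapes, got {cset.k}")
    X = cset.shapes.reshape(cset.k, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    m = min(cset.k - 1, Xc.shape[1])
    s = s[:m]
    eigenvalues = s**2 / (cset.k - 1)
    modes = _fix_mode_signs(Vt[:m].T)
    return ShapeModel(
        mean_vector=mean,
        modes=modes,
        eigenvalues=eigenvalues,
        n_training=cset.k,
        template=cset.template,
        metadata=dict(metadata or {}),
    )


def variance_table(model: ShapeModel, n_modes: int = 5) -> VarianceTable:
    """Percent variance per mode (A) and cumulative (B) for the first
    ``n_modes`` modes. Raises on an all-zero spectrum."""
    total = model.eigenvalues.sum()
    if total <= 0:
        raise ValueError("all eigenvalues are zero; variance percentages undefined")
    n = min(n_modes, model.n_modes)
    a = 100.0 * model.eigenvalues[:n] / total
    b = np.cumsum(100.0 * model.eigenvalues / total)[:n]
    return VarianceTable(a, b)


def sample_mode(model: ShapeModel, mode_index: int, k_sd: float) -> TriangleMesh:
    """Shape at ``k_sd`` standard deviations along one mode (1-based index):
    mean + k_sd * sqrt(lambda_i) * mode_i."""
    if not (1 <= mode_index <= model.n_modes):
        raise IndexError(f"mode index {mode_index} out of range 1..{model.n_modes}")
    i = mode_index - 1
    vec = model.mean_vector + k_sd * np.sqrt(model.eigenvalues[i]) * model.modes[:, i]
    return model.template.with_vertices(vec.reshape(-1, 3))


def project(model: ShapeModel, shape: np.ndarray) -> np.ndarray:
    """Mode coefficients of a shape, in per-mode SD units
    (b_i = mode_i . (x - mean) / sqrt(lambda_i); zero where lambda_i = 0)."""
    x = np.asarray(shape, dtype=np.float64).ravel()
    if x.shape != model.mean_vector.shape:
        raise ValueError(f"shape has {x.size} coordinates, model expects {model.mean_vector.size}")
    raw = model.modes.T @ (x - model.mean_vector)
    sd = np.sqrt(model.eigenvalues)
    nonzero = model.eigenvalues > _EIG_TOL * max(model.eigenvalues.max(initial=0.0), 1.0)
    b = np.zeros_like(raw)
    b[nonzero] = raw[nonzero] / sd[nonzero]
    return b


def reconstruct(model: ShapeModel, coefficients: np.ndarray) -> TriangleMesh:
    """Shape from SD-unit mode coefficients: mean + sum b_i sqrt(lambda_i) mode_i."""
    b = np.asarray(coefficients, dtype=np.float64).ravel()
    if len(b) > model.n_modes:
        raise ValueError(f"{len(b)} coefficients for {model.n_modes} modes")
    vec = model.mean_vector + model.modes[:, : len(b)] @ (b * np.sqrt(model.eigenvalues[: len(b)]))
    return model.template.with_vertices(vec.reshape(-1, 3))


def save_model(model: ShapeModel, directory) -> Path:
    """Serialize a model as a portable directory: mean mesh (PLY), the
    modes/eigenvalues arrays (npz) and a JSON metadata sidecar."""
    from .mesh import write_mesh

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_mesh(model.mean_mesh(), directory / "mean.ply")
    np.savez(
        directory / "model.npz",
        mean_vector=model.mean_vector,
        modes=model.modes,
        eigenvalues=model.eigenvalues,
        template_vertices=model.template.vertices,
        template_faces=model.template.faces,
    )
    meta = dict(model.metadata)
    meta.update({"n_training": model.n_training, "n_modes": model.n_modes, "n_points": model.n_points})
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_model(directory) -> ShapeModel:
    directory = Path(directory)
    arrays = np.load(directory / "model.npz")
    meta = json.loads((directory / "metadata.json").read_text())
    template = TriangleMesh(arrays["template_vertices"], arrays["template_faces"])
    template.aligned = True
    n_training = meta.pop("n_training")
    meta.pop("n_modes", None)
    meta.pop("n_points", None)
    return ShapeModel(
        mean_vector=arrays["mean_vector"],
        modes=arrays["modes"],
        eigenvalues=arrays["eigenvalues"],
        n_training=n_training,
        template=template,
        metadata=meta,
    )
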