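"""Shared fixtures: small analytic meshes and one session-scoped synthetic
femur population (coarse resolution so the whole suite stays fast)."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from ossa.mesh import TriangleMesh
from ossa.synthetic import BonePopulationSpec, generate_bone_population


@pytest.fixture(scope="session")
def icosphere10():
    """Fine icosphere, radius 10 mm."""
    return TriangleMesh.from_trimesh(trimesh.creation.icosphere(subdivisions=4, radius=10.0))


@pytest.fixture(scope="session")
def icosphere_coarse():
    return TriangleMesh.from_trimesh(trimesh.creation.icosphere(subdivisions=2, radius=10.0))


@pytest.fixture
def tetrahedron():
    v = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(v, f)


@pytest.fixture(scope="session")
def femur_population():
    """n=12 femur population at coarse resolution, reference conditions."""
    spec = BonePopulationSpec(n=12, seed=7, resolution=2.0)
    meshes, records, landmarks = generate_bone_population(spec)
    return spec, meshes, records, landmarks


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
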