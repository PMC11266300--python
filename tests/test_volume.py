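import numpy as np
import pytest
from scipy import ndimage

from ossa.anatomy import fit_sphere
from ossa.geometry import closest_point_on_mesh
from ossa.mesh import TriangleMesh
from ossa.synthetic import BonePopulationSpec, generate_bone_population, voxelize_mesh
from ossa.volume import (
    BinaryMask,
    EmptySegmentationError,
    VoxelVolume,
    extract_surface,
    morphological_close,
    threshold_segment,
)


def ball_volume(radius=10.0, spacing=1.0, value=1000.0, margin=3):
    n = int(2 * (radius + margin * spacing) / spacing) + 1
    coords = (np.arange(n) - (n - 1) / 2) * spacing
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    data = np.where(X**2 + Y**2 + Z**2 <= radius**2, value, 0.0)
    origin = np.full(3, coords[0])
    return VoxelVolume(data, np.full(3, spacing), origin)


class TestThreshold:
    def test_uniform_volume_fully_foreground(self):
        vol = VoxelVolume(np.full((4, 4, 4), 1000.0), np.ones(3), np.zeros(3))
        assert threshold_segment(vol, 350).count() == 64

    def test_threshold_is_inclusive(self):
        data = np.zeros((3, 3, 3))
        data[1, 1, 1] = 350.0
        mask = threshold_segment(VoxelVolume(data, np.ones(3), np.zeros(3)), 350)
        assert mask.data[1, 1, 1]
        assert mask.count() == 1

    def test_ball_count_matches_bruteforce_voxel_centers(self):
        vol = ball_volume(radius=10.0, spacing=1.0)
        count = threshold_segment(vol, 350).count()
        # independent oracle: count voxel centers inside the analytic ball
        n = vol.data.shape[0]
        coords = (np.arange(n) - (n - 1) / 2) * 1.0
        X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
        oracle = int((X**2 + Y**2 + Z**2 <= 100.0).sum())
        assert count == oracle
        assert abs(count - 4 / 3 * np.pi * 1000) / (4 / 3 * np.pi * 1000) < 0.02

    def test_monotone_in_threshold(self, rng):
        data = rng.uniform(0, 1000, (8, 8, 8))
        vol = VoxelVolume(data, np.ones(3), np.zeros(3))
        lo = threshold_segment(vol, 200).data
        hi = threshold_segment(vol, 600).data
        assert (hi <= lo).all()

    def test_nonfinite_threshold_rejected(self):
        vol = VoxelVolume(np.zeros((3, 3, 3)), np.ones(3), np.zeros(3))
        with pytest.raises(ValueError, match="finite"):
            threshold_segment(vol, np.nan)


class TestClosing:
    def test_empty_mask_stays_empty(self):
        mask = BinaryMask(np.zeros((6, 6, 6), bool), np.ones(3), np.zeros(3))
        assert morphological_close(mask, 3.0).count() == 0

    def test_idempotent(self, rng):
        data = rng.random((10, 10, 10)) > 0.7
        mask = BinaryMask(data, np.ones(3), np.zeros(3))
        once = morphological_close(mask, 3.0)
        twice = morphological_close(once, 3.0)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_single_voxel_cavity_filled_matches_bruteforce(self):
        vol = ball_volume(radius=6.0, spacing=1.0)
        data = vol.data >= 350
        c = data.shape[0] // 2
        data[c, c, c] = False
        mask = BinaryMask(data, vol.spacing, vol.origin)
        closed = morphological_close(mask, 3.0)
        assert closed.data[c, c, c]
        # brute-force oracle: explicit dilation then erosion, same element
        off = np.arange(-1, 2)
        X, Y, Z = np.meshgrid(off, off, off, indexing="ij")
        elem = X**2 + Y**2 + Z**2 <= 1.5**2
        pad = np.pad(data, 2)
        oracle = ndimage.binary_erosion(ndimage.binary_dilation(pad, elem), elem)[2:-2, 2:-2, 2:-2]
        np.testing.assert_array_equal(closed.data, oracle)

    def test_subvoxel_kernel_warns_and_returns_unchanged(self):
        mask = BinaryMask(np.ones((4, 4, 4), bool), np.full(3, 5.0), np.zeros(3))
        with pytest.warns(UserWarning, match="below one voxel"):
            out = morphological_close(mask, 3.0)
        np.testing.assert_array_equal(out.data, mask.data)


class TestExtractSurface:
    def test_ball_surface_area_and_topology(self):
        mask = threshold_segment(ball_volume(radius=10.0, spacing=1.0), 350)
        mesh = extract_surface(mask)
        assert mesh.is_manifold()
        assert mesh.euler_characteristic() == 2
        assert abs(mesh.area() - 4 * np.pi * 100) / (4 * np.pi * 100) < 0.05

    def test_ball_radius_recovered_within_one_voxel(self):
        mask = threshold_segment(ball_volume(radius=10.0, spacing=1.0), 350)
        sphere = fit_sphere(extract_surface(mask).vertices)
        assert abs(sphere.radius - 10.0) < 1.0
        assert np.abs(sphere.center).max() < 1.0

    def test_two_balls_give_two_components_largest_selectable(self):
        n = 40
        coords = np.arange(n) * 1.0
        X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
        data = ((X - 10) ** 2 + (Y - 10) ** 2 + (Z - 10) ** 2 <= 64) | (
            (X - 30) ** 2 + (Y - 30) ** 2 + (Z - 30) ** 2 <= 16
        )
        mask = BinaryMask(data, np.ones(3), np.zeros(3))
        mesh = extract_surface(mask)
        assert len(mesh.as_trimesh().split(only_watertight=False)) == 2
        largest = extract_surface(mask, largest_component=True)
        assert len(largest.as_trimesh().split(only_watertight=False)) == 1
        s = fit_sphere(largest.vertices)
        assert s.radius == pytest.approx(8.0, abs=1.0)

    def test_empty_mask_raises(self):
        mask = BinaryMask(np.zeros((4, 4, 4), bool), np.ones(3), np.zeros(3))
        with pytest.raises(EmptySegmentationError):
            extract_surface(mask)

    def test_anisotropic_spacing_scales_world_coordinates(self):
        mask = threshold_segment(ball_volume(radius=10.0, spacing=1.0), 350)
        aniso = BinaryMask(mask.data, np.array([1.0, 1.0, 2.0]), mask.origin)
        mesh = extract_surface(aniso)
        extent = np.ptp(mesh.vertices, axis=0)
        assert extent[2] == pytest.approx(2 * extent[0], rel=0.1)


def test_full_chain_on_synthetic_bone_within_two_voxels():
    """voxelize -> threshold -> close -> surface stays within 2x spacing of
    the source bone surface (one-sided Hausdorff, both directions)."""
    spec = BonePopulationSpec(n=2, seed=3, resolution=2.0)
    bone = generate_bone_population(spec)[0][0]
    spacing = 1.5
    vol = voxelize_mesh(bone, spacing=spacing)
    mask = morphological_close(threshold_segment(vol, 350), 3.0)
    recon = extract_surface(mask)
    _, d1, _ = closest_point_on_mesh(bone.vertices, bone.faces, recon.vertices)
    _, d2, _ = closest_point_on_mesh(recon.vertices, recon.faces, bone.vertices)
    assert max(d1.max(), d2.max()) <= 2.0 * spacing
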