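import numpy as np
import pytest

from ossa.correspondence import CorrespondedSet
from ossa.mesh import TriangleMesh
from ossa.ssm import (
    ShapeModel,
    build_ssm,
    project,
    reconstruct,
    round_sig,
    sample_mode,
    save_model,
    load_model,
    variance_table,
)


def make_set(shapes, template=None):
    shapes = np.asarray(shapes, dtype=float)
    if template is None:
        v = shapes[0]
        faces = np.array([[0, 1, 2], [0, 2, 3]])
        template = TriangleMesh(v, faces)
        template.aligned = True
    return CorrespondedSet(template=template, shapes=shapes, ids=[str(i) for i in range(len(shapes))])


@pytest.fixture
def quad_shapes(rng):
    return rng.normal(scale=5.0, size=(6, 4, 3))


class TestBuildSSM:
    def test_identical_shapes_zero_spectrum(self):
        shape = np.arange(12.0).reshape(4, 3)
        model = build_ssm(make_set([shape] * 4))
        np.testing.assert_allclose(model.eigenvalues, 0, atol=1e-20)
        np.testing.assert_allclose(model.mean_vector, shape.ravel())

    def test_two_shapes_single_mode_eigenvalue(self, rng):
        x1, x2 = rng.normal(size=(2, 4, 3))
        model = build_ssm(make_set([x1, x2]))
        # hand computation: with 1/(K-1) normalization the single nonzero
        # eigenvalue is ||x1 - x2||^2 / 2
        expected = np.sum((x1 - x2) ** 2) / 2.0
        assert model.eigenvalues[0] == pytest.approx(expected, rel=1e-12)
        assert model.n_modes == 1

    def test_matches_eigendecomposition_oracle(self, rng):
        shapes = rng.normal(size=(10, 20, 3))
        model = build_ssm(make_set(shapes, template=TriangleMesh(shapes[0], np.array([[0, 1, 2]]))))
        X = shapes.reshape(10, -1)
        C = np.cov(X, rowvar=False, ddof=1)
        w, V = np.linalg.eigh(C)
        w = w[::-1][:9]
        V = V[:, ::-1][:, :9]
        np.testing.assert_allclose(model.eigenvalues, w, atol=1e-8)
        # modes equal up to sign
        dots = np.abs(np.einsum("ij,ij->j", model.modes, V))
        np.testing.assert_allclose(dots, 1.0, atol=1e-8)

    def test_modes_orthonormal_and_sorted(self, quad_shapes):
        model = build_ssm(make_set(quad_shapes))
        G = model.modes.T @ model.modes
        assert np.abs(G - np.eye(model.n_modes)).max() < 1e-8
        assert (np.diff(model.eigenvalues) <= 1e-12).all()

    def test_single_shape_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            build_ssm(make_set([np.zeros((4, 3))] * 1))


class TestVarianceTable:
    def _model_with_eigenvalues(self, eigs):
        eigs = np.asarray(eigs, dtype=float)
        m = len(eigs)
        n = 3 * max(2, (m + 5) // 3 + 2)
        modes = np.eye(n)[:, :m]
        tmpl = TriangleMesh(np.arange(n, dtype=float).reshape(-1, 3), np.array([[0, 1, 2]]))
        return ShapeModel(np.zeros(n), modes, eigs, n_training=m + 1, template=tmpl)

    def test_reference_spectrum_reproduces_published_rounding(self):
        # leading five eigenvalues plus a 0.26% remainder tail
        model = self._model_with_eigenvalues([93.5, 5.62, 0.34, 0.17, 0.11, 0.1, 0.1, 0.06])
        vt = variance_table(model, n_modes=5)
        a, b = vt.rounded()
        np.testing.assert_allclose(a, [93.5, 5.62, 0.34, 0.17, 0.11])
        np.testing.assert_allclose(b, [93.5, 99.1, 99.5, 99.6, 99.7])

    def test_uniform_spectrum(self):
        vt = variance_table(self._model_with_eigenvalues([2.0, 2.0, 2.0, 2.0]), n_modes=4)
        np.testing.assert_allclose(vt.per_mode, 25.0)
        np.testing.assert_allclose(vt.cumulative, [25, 50, 75, 100])

    def test_single_nonzero_eigenvalue(self):
        vt = variance_table(self._model_with_eigenvalues([3.7, 0.0]), n_modes=5)
        np.testing.assert_allclose(vt.per_mode[0], 100.0)
        np.testing.assert_allclose(vt.cumulative[-1], 100.0)

    def test_total_spectrum_sums_to_100(self, quad_shapes):
        model = build_ssm(make_set(quad_shapes))
        vt = variance_table(model, n_modes=model.n_modes)
        assert vt.cumulative[-1] == pytest.approx(100.0, abs=1e-6)
        assert (np.diff(vt.cumulative) >= -1e-12).all()

    def test_zero_spectrum_rejected(self):
        model = build_ssm(make_set([np.arange(12.0).reshape(4, 3)] * 3))
        with pytest.raises(ValueError, match="zero"):
            variance_table(model)


class TestModeShapes:
    def test_zero_sd_returns_mean(self, quad_shapes):
        model = build_ssm(make_set(quad_shapes))
        mesh = sample_mode(model, 1, 0.0)
        np.testing.assert_allclose(mesh.vertices.ravel(), model.mean_vector, atol=1e-12)

    def test_plus_minus_three_sd_mirror_about_mean(self, quad_shapes):
        model = build_ssm(make_set(quad_shapes))
        sp = sample_mode(model, 2, 3.0).vertices
        sm = sample_mode(model, 2, -3.0).vertices
        np.testing.assert_allclose((sp + sm) / 2, model.mean_vector.reshape(-1, 3), atol=1e-9)

    def test_mode_index_out_of_range(self, quad_shapes):
        model = build_ssm(make_set(quad_shapes))
        with pytest.raises(IndexError):
            sample_mode(model, model.n_modes + 1, 1.0)

    def test_scale_mode_orders_centroid_size(self, rng):
        base = rng.normal(scale=5.0, size=(4, 3))
        # orient the base so the sign convention (largest-magnitude mode
        # component positive) makes +SD the enlarging direction
        flat = base.ravel()
        if flat[np.abs(flat).argmax()] < 0:
            base = -base
        shapes = [base * np.exp(s) for s in rng.normal(0, 0.1, 12)]
        model = build_ssm(make_set(shapes))
        up = sample_mode(model, 1, 3.0)
        down = sample_mode(model, 1, -3.0)
        assert up.centroid_size() > down.centroid_size()


class TestProjection:
    def test_mean_projects_to_zero(self, quad_shapes):
        model = build_ssm(make_set(quad_shapes))
        np.testing.assert_allclose(project(model, model.mean_vector), 0, atol=1e-10)

    def test_training_shape_round_trip(self, quad_shapes):
        model = build_ssm(make_set(quad_shapes))
        x = quad_shapes[2]
        back = reconstruct(model, project(model, x))
        np.testing.assert_allclose(back.vertices, x, atol=1e-8)

    def test_sampled_mode_projects_to_unit_coefficient(self, quad_shapes):
        model = build_ssm(make_set(quad_shapes))
        b = project(model, sample_mode(model, 2, 1.7).vertices)
        expected = np.zeros(model.n_modes)
        expected[1] = 1.7
        np.testing.assert_allclose(b, expected, atol=1e-8)

    def test_truncation_error_non_increasing(self, quad_shapes):
        model = build_ssm(make_set(quad_shapes))
        x = quad_shapes[4]
        b = project(model, x)
        errs = [
            np.linalg.norm(reconstruct(model, b[:k]).vertices - x)
            for k in range(model.n_modes + 1)
        ]
        assert all(e2 <= e1 + 1e-9 for e1, e2 in zip(errs, errs[1:]))


def test_round_sig_three_significant_figures():
    np.testing.assert_allclose(round_sig([99.123, 5.678, 0.3456, 0.0]), [99.1, 5.68, 0.346, 0.0])


def test_model_save_load_round_trip(tmp_path, quad_shapes):
    model = build_ssm(make_set(quad_shapes), metadata={"group": "g", "side": "left"})
    save_model(model, tmp_path / "m")
    back = load_model(tmp_path / "m")
    np.testing.assert_allclose(back.mean_vector, model.mean_vector)
    np.testing.assert_allclose(back.modes, model.modes)
    np.testing.assert_allclose(back.eigenvalues, model.eigenvalues)
    assert back.metadata["group"] == "g"
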