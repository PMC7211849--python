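"""GPA alignment, shape PCA, landmark contributions and TPS warps."""

import numpy as np
import pytest

from scarabwing.morphometrics import (
    GeneralizedProcrustesAnalysis,
    ShapePCA,
    centroid_size,
    deformation_grid,
    gpa,
    landmark_contributions,
    shape_pca,
    tps_warp,
)
from scarabwing.simulate import default_ancestral_shape


def _similarity(config, rng):
    th = rng.uniform(0, 2 * np.pi)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return rng.uniform(0.3, 3.0) * config @ R.T + rng.normal(scale=5.0, size=2)


class TestGPA:
    def test_similarity_copies_align_identically(self, rng):
        base = default_ancestral_shape()
        shapes = np.stack([_similarity(base, rng) for _ in range(6)])
        res = gpa(shapes)
        for i in range(1, 6):
            np.testing.assert_allclose(res.aligned[i], res.aligned[0], atol=1e-10)
        assert np.all(res.procrustes_distances < 1e-10)

    def test_scaled_pair_zero_procrustes_distance(self):
        base = default_ancestral_shape()
        res = gpa(np.stack([base, 2.5 * base]))
        assert np.all(res.procrustes_distances < 1e-12)

    def test_aligned_configurations_centred_unit_size(self, rng):
        base = default_ancestral_shape()
        shapes = np.stack([base + 0.02 * rng.normal(size=base.shape) for _ in range(8)])
        res = gpa(shapes)
        for a in res.aligned:
            assert np.linalg.norm(a.mean(axis=0)) < 1e-10
            assert centroid_size(a) == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(res.aligned.mean(axis=0), res.mean_shape, atol=1e-12)

    def test_output_invariant_to_input_similarity_transforms(self, rng):
        base = default_ancestral_shape()
        shapes = np.stack([base + 0.02 * rng.normal(size=base.shape) for _ in range(8)])
        res0 = gpa(shapes)
        shapes2 = np.stack([_similarity(c, rng) for c in shapes])
        res1 = gpa(shapes2)
        assert np.abs(res0.aligned - res1.aligned).max() < 1e-8
        assert np.abs(res0.mean_shape - res1.mean_shape).max() < 1e-8

    def test_constructed_mean_recovered(self, rng):
        # shapes = mean +/- paired tangent-space perturbations average to the
        # constructed mean exactly; GPA recovers it to second order
        m = default_ancestral_shape()
        m = m - m.mean(axis=0)
        m /= np.linalg.norm(m)
        rot90 = np.column_stack([-m[:, 1], m[:, 0]])
        deltas = []
        for _ in range(4):
            d = rng.normal(size=m.shape)
            d -= d.mean(axis=0)
            for basis in (m, rot90):
                d -= (np.sum(d * basis) / np.sum(basis * basis)) * basis
            deltas.append(1e-4 * d / np.linalg.norm(d))
        shapes = np.stack([m + s * d for d in deltas for s in (+1, -1)])
        res = gpa(shapes)
        # compare up to the canonical rotation applied by the aligner
        u, _, vt = np.linalg.svd(m.T @ res.mean_shape)
        R = (u @ vt).T
        assert np.abs(m @ R.T - res.mean_shape).max() < 1e-6

    def test_degenerate_configuration_rejected(self):
        flat = np.zeros((4, 25, 2))
        with pytest.raises(ValueError, match="degenerate"):
            gpa(flat)

    def test_transform_aligns_new_configurations(self, rng):
        base = default_ancestral_shape()
        shapes = np.stack([base + 0.02 * rng.normal(size=base.shape) for _ in range(6)])
        est = GeneralizedProcrustesAnalysis().fit(shapes)
        new = _similarity(shapes[0], rng)
        aligned = est.transform(new)
        np.testing.assert_allclose(aligned, est.aligned_[0], atol=1e-8)


class TestShapePCA:
    def test_identical_specimens_zero_eigenvalues(self):
        base = default_ancestral_shape()
        res = shape_pca(np.stack([base] * 5))
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-20)

    def test_known_displacement_axis_found(self, rng):
        base = default_ancestral_shape().reshape(-1)
        v = rng.normal(size=base.size)
        v /= np.linalg.norm(v)
        X = np.stack(
            [base + s * v + 1e-3 * rng.normal(size=base.size) for s in
             np.repeat([-0.5, 0.5], 10)]
        )
        res = shape_pca(X.reshape(20, 25, 2))
        cos = abs(res.loadings[0] @ v)
        assert cos > 0.99

    def test_percent_variance_sums_to_100(self, rng):
        X = rng.normal(size=(10, 25, 2))
        res = shape_pca(X)
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-8)

    def test_scores_orthogonal(self, rng):
        X = rng.normal(size=(12, 25, 2))
        res = shape_pca(X)
        gram = res.scores.T @ res.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_eigenvalues_non_increasing(self, rng):
        res = shape_pca(rng.normal(size=(15, 25, 2)))
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_too_few_specimens_rejected(self, rng):
        with pytest.raises(ValueError):
            ShapePCA().fit(rng.normal(size=(2, 50)))


class TestLandmarkContributions:
    def test_concentrated_loading(self):
        v = np.zeros(50)
        v[10:12] = [3.0, 4.0]  # landmark 6 only
        c = landmark_contributions(v)
        assert c[5] == pytest.approx(100.0)
        assert np.delete(c, 5).max() == 0.0

    def test_uniform_loading(self):
        c = landmark_contributions(np.ones(50))
        np.testing.assert_allclose(c, 4.0)
        assert c.sum() == pytest.approx(100.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            landmark_contributions(np.zeros(50))


class TestTPS:
    def test_identity_map(self):
        src = default_ancestral_shape()
        w = tps_warp(src, src)
        assert w.bending_energy < 1e-12
        pts = np.array([[0.3, 0.2], [-1.0, 0.5]])
        np.testing.assert_allclose(w.warp(pts), pts, atol=1e-9)

    def test_affine_reproduction(self, rng):
        src = default_ancestral_shape()
        for _ in range(5):
            A = rng.normal(size=(2, 2)) + np.eye(2)
            b = rng.normal(size=2)
            tgt = src @ A.T + b
            w = tps_warp(src, tgt)
            assert w.bending_energy < 1e-10
            pts = rng.normal(size=(20, 2))
            np.testing.assert_allclose(w.warp(pts), pts @ A.T + b, atol=1e-8)

    def test_exact_interpolation_of_random_targets(self, rng):
        src = default_ancestral_shape()
        tgt = src + 0.1 * rng.normal(size=src.shape)
        w = tps_warp(src, tgt)
        assert np.abs(w.warp(src) - tgt).max() < 1e-9
        assert w.bending_energy >= 0

    def test_bending_energy_rigid_invariance(self, rng, rotation_2d):
        src = default_ancestral_shape()
        tgt = src + 0.1 * rng.normal(size=src.shape)
        e0 = tps_warp(src, tgt).bending_energy
        R = rotation_2d(rng.uniform(0, 2 * np.pi))
        shift = rng.normal(size=2)
        e1 = tps_warp(src @ R.T + shift, tgt @ R.T + shift).bending_energy
        assert e0 == pytest.approx(e1, rel=1e-8)

    def test_coincident_source_rejected(self):
        src = default_ancestral_shape()
        src[1] = src[0]
        with pytest.raises(ValueError, match="singular kernel"):
            tps_warp(src, src + 0.1)


class TestDeformationGrid:
    def test_identity_grid_undistorted(self):
        src = default_ancestral_shape()
        w = tps_warp(src, src)
        grid = deformation_grid(w, bounds=(-2, 2, -1, 1), n_grid=5, n_samples=5)
        line = np.asarray(grid["horizontal"][0])
        np.testing.assert_allclose(line[:, 1], line[0, 1], atol=1e-8)

    def test_translation_shifts_grid_rigidly(self):
        src = default_ancestral_shape()
        w = tps_warp(src, src + np.array([1.0, -0.5]))
        grid = deformation_grid(w, bounds=(-2, 2, -1, 1), n_grid=4, n_samples=4)
        g0 = deformation_grid(tps_warp(src, src), bounds=(-2, 2, -1, 1), n_grid=4, n_samples=4)
        shifted = np.asarray(g0["vertical"]) + np.array([1.0, -0.5])
        np.testing.assert_allclose(np.asarray(grid["vertical"]), shifted, atol=1e-8)

    def test_source_landmark_maps_to_target(self, rng):
        src = default_ancestral_shape()
        tgt = src + 0.05 * rng.normal(size=src.shape)
        w = tps_warp(src, tgt)
        np.testing.assert_allclose(w.warp(src[7]), tgt[7][None], atol=1e-9)
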