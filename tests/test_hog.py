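import numpy as np
import pytest

from cervitex.exceptions import ModelMismatchError, RankError
from cervitex.hog import (
    HogConfig,
    fit_pca,
    gradient_field,
    hog_cell_histograms,
    hog_descriptor,
    hog_per_image,
    raw_descriptor_length,
)
from cervitex.image_prep import HOG_WINDOW_SHAPE, RGBImage, prepare_hog_window

from .oracles import pca_eig_oracle


class TestGradientField:
    def test_three_four_five_triangle(self):
        # linear ramp 3/px along x plus 4/px along y
        rows, cols = np.mgrid[0:8, 0:8].astype(float)
        f = gradient_field(3.0 * cols + 4.0 * rows)
        interior = (slice(1, -1), slice(1, -1))
        np.testing.assert_allclose(f.g[interior], 5.0)
        np.testing.assert_allclose(
            f.theta[interior], np.degrees(np.arctan2(4.0, 3.0))
        )

    def test_constant_window_zero_magnitude(self):
        f = gradient_field(np.full((8, 8), 0.5))
        np.testing.assert_allclose(f.g, 0.0)

    def test_magnitude_identity_and_orientation_range(self, rng):
        f = gradient_field(rng.random((16, 16)))
        np.testing.assert_allclose(f.g, np.sqrt(f.gx**2 + f.gy**2))
        assert (f.theta >= 0).all() and (f.theta < 180).all()
        assert ((f.g == 0) == ((f.gx == 0) & (f.gy == 0))).all()

    def test_horizontal_step_edge_vertical_gradient(self):
        """A two-tone horizontal edge has a purely vertical gradient, matching
        hand-evaluated central differences on the edge rows."""
        w = np.zeros((4, 4))
        w[2:] = 1.0
        f = gradient_field(w)
        # central difference at rows 1 and 2: (w[r+1] - w[r-1]) / 2 = 0.5
        np.testing.assert_allclose(f.gy[1:3], 0.5)
        np.testing.assert_allclose(f.gx, 0.0)
        np.testing.assert_allclose(f.theta[1:3], 90.0)


class TestHogDescriptor:
    def test_constant_window_all_zero(self):
        d = hog_descriptor(np.full(HOG_WINDOW_SHAPE, 0.3))
        np.testing.assert_allclose(d, 0.0)

    def test_length_matches_closed_form(self):
        d = hog_descriptor(np.random.default_rng(0).random(HOG_WINDOW_SHAPE))
        assert d.shape == (raw_descriptor_length(),) == (3780,)

    def test_nondefault_geometry_length(self):
        cfg = HogConfig(cell=8, bins=6, block=2)
        d = hog_descriptor(np.random.default_rng(1).random((32, 32)), cfg)
        assert d.shape == (raw_descriptor_length((32, 32), cfg),)

    def test_votes_are_magnitude_weighted_and_nonnegative(self, rng):
        cells = hog_cell_histograms(rng.random((32, 32)))
        assert (cells >= 0).all()
        # total vote mass equals total gradient magnitude
        g = gradient_field(rng.random((32, 32)))  # fresh draw for independence
        cells2 = hog_cell_histograms(g.g * 0 + 0.0)  # zero field -> zero mass
        assert cells2.sum() == 0

    def test_180_rotation_permutes_cell_histograms(self, rng):
        """Unsigned orientations are invariant under 180-degree rotation, so
        the rotated window's cell grid is the reversed cell grid."""
        w = rng.random((16, 16))
        cells = hog_cell_histograms(w)
        cells_rot = hog_cell_histograms(np.rot90(w, 2).copy())
        np.testing.assert_allclose(cells_rot, cells[::-1, ::-1], atol=1e-10)


class TestPca:
    def test_twenty_components_default(self, rng):
        model = fit_pca(rng.random((40, 100)))
        assert model.n_components == 20
        assert model.components.shape == (20, 100)

    def test_loadings_orthonormal_and_variance_nonincreasing(self, rng):
        model = fit_pca(rng.random((50, 60)), k=10)
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(10), atol=1e-8)
        assert (np.diff(model.explained_variance) <= 1e-10).all()

    def test_rank_one_data(self, rng):
        base = rng.random(30)
        X = np.outer(rng.random(25), base) + rng.random(30)
        model = fit_pca(X, k=5)
        assert model.explained_variance[0] > 0
        np.testing.assert_allclose(model.explained_variance[1:], 0.0, atol=1e-10)

    def test_too_few_samples_raises_rank_error(self, rng):
        with pytest.raises(RankError, match="5"):
            fit_pca(rng.random((15, 30)), k=20)

    def test_projections_match_eigendecomposition_oracle(self, rng):
        X = rng.random((50, 200))
        model = fit_pca(X, k=8)
        mean, vals, vecs = pca_eig_oracle(X, 8)
        np.testing.assert_allclose(model.mean, mean, atol=1e-10)
        np.testing.assert_allclose(model.explained_variance, vals, atol=1e-8)
        proj = model.transform(X)
        proj_oracle = (X - mean) @ vecs.T
        for c in range(8):  # components agree up to sign
            s = np.sign(np.dot(proj[:, c], proj_oracle[:, c]))
            np.testing.assert_allclose(proj[:, c], s * proj_oracle[:, c], atol=1e-8)

    def test_shift_invariance_of_projections(self, rng):
        X = rng.random((30, 40))
        shifted = X + 7.5
        a = fit_pca(X, k=4)
        b = fit_pca(shifted, k=4)
        np.testing.assert_allclose(a.transform(X), b.transform(shifted), atol=1e-8)


class TestHogPerImage:
    def _images(self, rng, n):
        return [
            RGBImage(pixels=rng.integers(0, 256, (256, 128, 3), dtype=np.uint8))
            for _ in range(n)
        ]

    def test_length_20(self, rng):
        imgs = self._images(rng, 25)
        raws = np.vstack(
            [hog_descriptor(prepare_hog_window(im)) for im in imgs]
        )
        model = fit_pca(raws)
        assert hog_per_image(imgs[0], model).shape == (20,)

    def test_mean_vector_projects_to_zero(self, rng):
        model = fit_pca(rng.random((30, 50)), k=10)
        np.testing.assert_allclose(
            model.transform(model.mean[None, :]), 0.0, atol=1e-10
        )

    def test_round_trip_on_low_rank_data(self, rng):
        """Data lying in the span of <= k directions reconstructs exactly."""
        basis = rng.random((5, 40))
        X = rng.random((30, 5)) @ basis + rng.random(40)
        model = fit_pca(X, k=10)
        recon = model.inverse_transform(model.transform(X))
        np.testing.assert_allclose(recon, X, atol=1e-6)

    def test_dimension_mismatch_raises(self, rng):
        model = fit_pca(rng.random((30, 50)), k=5)
        with pytest.raises(ModelMismatchError):
            model.transform(rng.random((3, 49)))
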