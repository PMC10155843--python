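"""The eleven dimension-reduction schemes behind one fit/transform contract."""

import warnings

import numpy as np
import pytest

import skinhsi as sh
from skinhsi import dimred
from skinhsi.core import BandGrid

from conftest import make_table


class TestPCA:
    def test_line_data_explained_by_first_component(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=50)
        direction = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        table = make_table(np.outer(t, direction) + 7.0)
        model = dimred.fit_pca(table, 2)
        total = model.explained_variance_.sum()
        assert model.explained_variance_[0] / total > 1.0 - 1e-9

    def test_loadings_orthonormal(self, default_table):
        model = dimred.fit_pca(default_table, 5)
        L = model.components_
        assert np.allclose(L @ L.T, np.eye(5), atol=1e-8)

    def test_eigenvalues_match_dense_oracle(self):
        """20x5 table against a direct covariance eigendecomposition."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 5)) @ np.diag([3.0, 2.0, 1.0, 0.5, 0.1])
        table = make_table(X)
        model = dimred.fit_pca(table, 5)
        oracle = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        assert np.allclose(model.explained_variance_, oracle, atol=1e-10)

    def test_sign_convention_fixed(self):
        rng = np.random.default_rng(4)
        table = make_table(rng.normal(size=(30, 6)))
        model = dimred.fit_pca(table, 3)
        for comp in model.components_:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_k_exceeding_bands_rejected(self, default_table):
        with pytest.raises(ValueError):
            dimred.fit_pca(default_table, len(default_table.band_grid) + 1)

    def test_refit_reproducible(self, default_table):
        a = dimred.fit_pca(default_table, 3).transform(default_table.spectra)
        b = dimred.fit_pca(default_table, 3).transform(default_table.spectra)
        assert np.array_equal(a, b)


class TestClusterPCA:
    def test_single_cluster_equals_per_sample_pca(self, default_cube, default_table):
        model = dimred.fit_cluster_pca(default_cube, n=1, k=5, seed=0)
        pca = dimred.fit_pca(default_table, 5)
        assert np.allclose(model._fit_scores, pca.transform(default_table.spectra),
                           atol=1e-10)

    def test_score_stack_geometry(self, default_cube):
        model = dimred.fit_cluster_pca(default_cube, n=4, k=3, seed=0)
        stack = model.score_stack()
        assert stack.shape == default_cube.data.shape[:2] + (3,)
        assert np.all(stack[~default_cube.tissue_mask] == 0.0)

    def test_per_cluster_beats_global_reconstruction(self):
        """Two spectrally distinct populations: cluster-wise PCA at k=3 must
        reconstruct at least as well as one global PCA at k=3."""
        rng = np.random.default_rng(6)
        grid = BandGrid(np.linspace(420, 750, 20))
        h = w = 20
        base_a = 0.2 + 0.6 * rng.random(20)
        base_b = 0.2 + 0.6 * rng.random(20)
        dir_a, dir_b = rng.normal(size=(2, 3, 20)) * 0.05
        data = np.empty((h, w, 20))
        left = np.zeros((h, w), bool)
        left[:, : w // 2] = True
        for r in range(h):
            for c in range(w):
                if left[r, c]:
                    data[r, c] = base_a + rng.normal(size=3) @ dir_a
                else:
                    data[r, c] = base_b + rng.normal(size=3) @ dir_b
        cube = sh.ReflectanceCube(data, grid, tissue_mask=np.ones((h, w), bool))
        table = sh.flatten(cube)
        X = table.spectra

        model = dimred.fit_cluster_pca(cube, n=2, k=3, seed=0)
        # reconstruct through each pixel's own cluster model
        from skinhsi.unmixing import sam_matrix

        recon = np.empty_like(X)
        fitted = np.array(sorted(model.cluster_models))
        angles = sam_matrix(X, model.endmembers.spectra)
        labels = fitted[np.argmin(angles[:, fitted], axis=1)]
        for lab, m in model.cluster_models.items():
            idx = np.nonzero(labels == lab)[0]
            recon[idx] = m.inverse_transform(m.transform(X[idx]))
        cluster_mse = np.mean((recon - X) ** 2)

        g = dimred.fit_pca(table, 3)
        global_mse = np.mean((g.inverse_transform(g.transform(X)) - X) ** 2)
        assert cluster_mse <= global_mse + 1e-12

    def test_deterministic_under_seed(self, default_cube):
        a = dimred.fit_cluster_pca(default_cube, n=4, k=3, seed=5)._fit_scores
        b = dimred.fit_cluster_pca(default_cube, n=4, k=3, seed=5)._fit_scores
        assert np.array_equal(a, b)


class TestSuperPCA:
    def test_single_superpixel_equals_per_sample_pca(self, default_cube, default_table):
        model = dimred.fit_super_pca(default_cube, 1, 5, seed=0)
        pca = dimred.fit_pca(default_table, 5)
        assert np.allclose(model._fit_scores, pca.transform(default_table.spectra),
                           atol=1e-10)

    def test_requested_20_superpixels_achieved_within_contract(self, default_cube):
        model = dimred.fit_super_pca(default_cube, 20, 3, seed=0)
        assert 10 <= model.achieved_superpixels <= 30

    def test_scores_come_from_own_superpixel_loadings(self, default_cube):
        """Spot-check one superpixel against a direct projection."""
        model = dimred.fit_super_pca(default_cube, 12, 3, seed=0)
        table = sh.flatten(default_cube)
        labels = model.segment_labels_[table.coords[:, 0], table.coords[:, 1]]
        lab = next(iter(model.segment_models))
        idx = np.nonzero(labels == lab)[0]
        m = model.segment_models[lab]
        direct = (table.spectra[idx] - m.mean_) @ m.components_.T
        assert np.allclose(model._fit_scores[idx, : m.k], direct, atol=1e-10)

    def test_zero_superpixels_rejected(self, default_cube):
        with pytest.raises(ValueError):
            dimred.fit_super_pca(default_cube, 0, 3)


class TestMultiscale:
    @pytest.mark.parametrize("scales", [[9, 14, 20, 28, 40], [2, 5, 6, 8, 10]])
    def test_one_block_per_scale(self, default_cube, scales):
        kind = "super" if scales[0] == 9 else "cluster"
        model = dimred.fit_multiscale(default_cube, scales, k=3, kind=kind, seed=0)
        stacks = model.score_stacks()
        assert len(stacks) == 5
        for s in stacks:
            assert s.shape == default_cube.data.shape[:2] + (3,)

    def test_duplicate_scales_deduplicated(self, default_cube):
        with pytest.warns(UserWarning, match="duplicate"):
            model = dimred.fit_multiscale(default_cube, [4, 4], k=2, kind="cluster")
        assert len(model.models) == 1


class TestMSelect:
    def test_two_features_on_default_grid(self, default_table):
        model = dimred.fit_mselect(default_table.band_grid)
        assert model.k == 2
        assert model.transform(default_table.spectra).shape == (len(default_table), 2)

    def test_exact_targets_chosen_when_on_grid(self):
        grid = BandGrid(np.array([430.0, 540.0, 600.0, 650.0, 740.0]))
        model = dimred.fit_mselect(grid)
        assert np.array_equal(model.band_indices, [1, 3])

    def test_nearest_bands_within_half_spacing(self):
        model = dimred.fit_mselect(BandGrid.default())
        chosen = BandGrid.default().wavelengths[model.band_indices]
        assert np.all(np.abs(chosen - np.array([540.0, 650.0])) <= 0.54)

    def test_target_outside_grid_rejected(self):
        grid = BandGrid(np.linspace(560.0, 750.0, 50))
        with pytest.raises(ValueError, match="540"):
            dimred.fit_mselect(grid)


class TestLDA:
    @staticmethod
    def gaussian_classes(sep=8.0, n=300, d=8, seed=2):
        rng = np.random.default_rng(seed)
        X0 = rng.normal(size=(n, d))
        X1 = rng.normal(size=(n, d))
        X1[:, 2] += sep
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        return make_table(np.vstack([X0, X1]), y)

    def test_binary_problem_gives_one_dimension(self):
        table = self.gaussian_classes()
        model = dimred.fit_lda(table)
        assert model.k == 1
        assert model.transform(table.spectra).shape[1] == 1

    def test_separated_classes_project_far_apart(self):
        table = self.gaussian_classes(sep=8.0)
        z = dimred.fit_lda(table).transform(table.spectra).ravel()
        y = table.labels
        pooled_sd = np.sqrt((z[y == 0].var(ddof=1) + z[y == 1].var(ddof=1)) / 2)
        assert abs(z[y == 1].mean() - z[y == 0].mean()) > 5 * pooled_sd

    def test_pca_lda_composition_is_one_dimensional(self):
        table = self.gaussian_classes()
        model = dimred.fit_lda(table, via_pca=5)
        assert model.method == "pcalda"
        assert model.transform(table.spectra).shape == (len(table), 1)

    def test_singular_scatter_advises_pca_lda(self):
        rng = np.random.default_rng(3)
        # rank-deficient: 10 samples in 20 dimensions
        X = rng.normal(size=(10, 20))
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        with pytest.raises(ValueError, match="PCA-LDA"):
            dimred.fit_lda(make_table(X, y))


class TestRFI:
    def test_importance_vector_spans_all_default_bands(self):
        rng = np.random.default_rng(1)
        n = 400
        X = rng.normal(size=(n, 311))
        y = (X[:, 100] > 0).astype(int)
        table = make_table(X, y, grid=BandGrid.default())
        model = dimred.fit_rfi(table, 5, n_estimators=20, seed=0)
        assert model.importances_.shape == (311,)

    def test_planted_signal_bands_dominate(self):
        """Class signal confined to 560-580 nm: all top-5 bands must fall in
        a 555-585 nm window."""
        grid = BandGrid.default()
        rng = np.random.default_rng(5)
        n = 1200
        X = rng.normal(size=(n, len(grid)))
        y = rng.integers(0, 2, n)
        window = (grid.wavelengths >= 560) & (grid.wavelengths <= 580)
        X[:, window] += y[:, None] * 1.5
        model = dimred.fit_rfi(make_table(X, y, grid=grid), 5, seed=0)
        chosen_nm = grid.wavelengths[model.band_indices]
        assert np.all((chosen_nm >= 555) & (chosen_nm <= 585))

    def test_null_labels_do_not_mimic_planted_signal(self):
        """Under label-noise the boosted importance must be far weaker than
        with a planted signal, and not concentrated in the signal window."""
        grid = BandGrid.default()
        rng = np.random.default_rng(6)
        n = 800
        X = rng.normal(size=(n, len(grid)))
        y_null = rng.integers(0, 2, n)
        null = dimred.fit_rfi(make_table(X.copy(), y_null, grid=grid), 5,
                              n_estimators=40, seed=0)
        window = (grid.wavelengths >= 560) & (grid.wavelengths <= 580)
        Xs = X.copy()
        Xs[:, window] += y_null[:, None] * 1.5
        signal = dimred.fit_rfi(make_table(Xs, y_null, grid=grid), 5,
                                n_estimators=40, seed=0)
        assert signal.importances_[window].sum() > 3 * null.importances_[window].sum()
        null_nm = grid.wavelengths[null.band_indices]
        assert not np.all((null_nm >= 555) & (null_nm <= 585))

    def test_k_exceeding_bands_rejected(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.normal(size=(50, 10)), rng.integers(0, 2, 50))
        with pytest.raises(ValueError):
            dimred.fit_rfi(table, 11)


class TestICAAndAutoencoder:
    def test_fastica_recovers_independent_sources(self):
        t = np.linspace(0, 8 * np.pi, 1000)
        S = np.column_stack([np.sin(t), np.sign(np.cos(3 * t))])
        X = S @ np.array([[1.0, 0.5], [0.4, 1.2]]).T
        model = dimred.fit_ica(make_table(X), 2, flavor="fast", seed=0)
        rec = model.transform(X)
        corr = np.abs(np.corrcoef(np.column_stack([S, rec]).T)[:2, 2:])
        assert corr.max(axis=1).min() > 0.95  # each source matched up to sign/permutation

    @pytest.mark.parametrize("flavor", ["fast", "reconstruction"])
    def test_transform_has_k_columns(self, flavor):
        rng = np.random.default_rng(2)
        table = make_table(rng.normal(size=(200, 12)))
        model = dimred.fit_ica(table, 4, flavor=flavor, seed=0)
        assert model.transform(table.spectra).shape == (200, 4)

    def test_autoencoder_capacity_monotonicity(self):
        """With linear activations, a full-width bottleneck reconstructs
        better than any narrower one."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(400, 8)) @ rng.normal(size=(8, 8))
        table = make_table(X)
        mses = {
            k: dimred.fit_autoencoder(table, k, seed=0, activation="identity",
                                      max_iter=400).reconstruction_mse_
            for k in (2, 4, 8)
        }
        assert mses[8] < mses[4] < mses[2]

    def test_autoencoder_transform_shape_and_determinism(self):
        rng = np.random.default_rng(8)
        table = make_table(rng.normal(size=(150, 10)))
        a = dimred.fit_autoencoder(table, 3, seed=1)
        b = dimred.fit_autoencoder(table, 3, seed=1)
        assert a.transform(table.spectra).shape == (150, 3)
        assert np.array_equal(a.transform(table.spectra), b.transform(table.spectra))


class TestEigenvectorChromophoreSignatures:
    def test_first_eigenvector_tracks_flat_base_spectrum(self, default_table):
        model = dimred.fit_pca(default_table, 3)
        b = len(default_table.band_grid)
        flat = np.ones(b) / np.sqrt(b)
        assert abs(model.components_[0] @ flat) > 0.8

    def test_early_eigenvector_shows_hbo2_twin_peaks(self, default_table):
        model = dimred.fit_pca(default_table, 3)
        hits = [dimred.has_twin_peak_signature(c, default_table.band_grid)
                for c in model.components_]
        assert any(hits)
        assert hits[2]  # the hemoglobin component surfaces by the third eigenvector

    def test_no_twin_peaks_without_hemoglobin(self):
        cfg = sh.SceneConfig(
            seed=3, base_concentrations={"melanin": 0.8, "hbo2": 0.0, "hb": 0.0},
            n_blood_stains=0, hemoglobin_multiplier=1.0,
        )
        cube = sh.generate_scene(cfg).to_reflectance_cube()
        model = dimred.fit_pca(sh.flatten(cube), 3)
        assert not any(dimred.has_twin_peak_signature(c, cube.band_grid)
                       for c in model.components_)
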