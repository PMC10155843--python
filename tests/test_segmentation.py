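"""SVM training, grouped cross-validation, fusion and dimension sweeps."""

from collections import Counter

import numpy as np
import pytest

import skinhsi as sh
from skinhsi.segmentation import (
    ClassifierConfig,
    fuse_multiscale,
    grouped_kfold,
    margin_violation_fraction,
    run_cv_experiment,
    sweep_dimensions,
    train_svm,
)


def blobs(n=200, sep=6.0, seed=2):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n, 2)), rng.normal(sep, 1, (n, 2))])
    y = np.r_[np.zeros(n, int), np.ones(n, int)]
    return X, y


class TestTrainSvm:
    def test_separable_blobs_high_training_accuracy(self):
        X, y = blobs()
        clf = train_svm(X, y)
        assert (clf.predict(X) == y).mean() >= 0.95

    def test_margin_violations_within_twice_budget(self):
        X, y = blobs()
        clf = train_svm(X, y, ClassifierConfig(outlier_fraction=0.05))
        assert margin_violation_fraction(clf, X, y) <= 0.10

    def test_deep_interior_point_classified_with_its_blob(self):
        X, y = blobs(sep=8.0)
        clf = train_svm(X, y)
        assert clf.predict([[0.0, 0.0]])[0] == 0
        assert clf.predict([[8.0, 8.0]])[0] == 1

    def test_single_class_rejected(self):
        X, _ = blobs()
        with pytest.raises(ValueError, match="single class"):
            train_svm(X, np.zeros(len(X), int))

    def test_invalid_outlier_fraction_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig(outlier_fraction=0.6)


class TestGroupedKFold:
    def test_sixteen_samples_five_folds(self):
        split = grouped_kfold([f"s{i}" for i in range(16)], 5, seed=0)
        sizes = sorted(Counter(split.fold_of.values()).values(), reverse=True)
        assert sizes == [4, 3, 3, 3, 3]

    def test_no_sample_crosses_folds(self):
        ids = [f"s{i}" for i in range(9)]
        split = grouped_kfold(ids, 3, seed=4)
        for fold in range(3):
            overlap = set(split.fold_samples(fold)) & set(split.train_samples(fold))
            assert not overlap
        assert sorted(sum((split.fold_samples(f) for f in range(3)), [])) == ids

    def test_five_samples_five_folds_one_each(self):
        split = grouped_kfold([f"s{i}" for i in range(5)], 5, seed=1)
        assert sorted(Counter(split.fold_of.values()).values()) == [1, 1, 1, 1, 1]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            grouped_kfold(["a", "b"], 5)

    def test_pixel_sample_ids_collapse_to_unique_samples(self):
        # per-pixel repetition of sample ids must not inflate fold counts
        ids = ["a"] * 50 + ["b"] * 30 + ["c"] * 20
        split = grouped_kfold(ids, 3, seed=0)
        assert len(split.fold_of) == 3


class TestFuseMultiscale:
    def test_majority_wins(self):
        votes = [np.array([1]), np.array([1]), np.array([0])]
        assert fuse_multiscale(votes)[0] == 1

    def test_tie_goes_to_non_tumor(self):
        votes = [np.array([1]), np.array([0])]
        assert fuse_multiscale(votes)[0] == 0

    def test_unanimous_agreement_is_identity(self):
        rng = np.random.default_rng(0)
        p = rng.integers(0, 2, 40)
        assert np.array_equal(fuse_multiscale([p, p, p]), p)

    def test_misaligned_shapes_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            fuse_multiscale([np.zeros(3, int), np.zeros(4, int)])


class TestRunCvExperiment:
    def test_metrics_have_one_row_per_fold(self, small_samples):
        res = run_cv_experiment(small_samples, "mselect", k=2, n_folds=5, seed=1,
                                max_train_pixels_per_sample=150)
        assert len(res.fold_metrics) == 5
        assert set(res.predictions) == {s.sample_id for s in small_samples}

    def test_predictions_respect_geometry(self, small_samples):
        res = run_cv_experiment(small_samples, "mselect", k=2, n_folds=5, seed=1,
                                max_train_pixels_per_sample=150)
        for s in small_samples:
            pred = res.predictions[s.sample_id]
            assert pred.shape == s.cube.data.shape[:2]
            assert not np.any(pred & ~s.cube.tissue_mask)

    def test_fixed_dimensionality_methods_override_k(self, small_samples):
        res = run_cv_experiment(small_samples, "mselect", k=50, n_folds=5, seed=1,
                                max_train_pixels_per_sample=150)
        assert res.k == 2

    def test_reducer_scope_respected_for_lda(self, small_samples):
        """Dataset-scope supervised reducer must run without leakage and
        produce a 1-D feature space."""
        res = run_cv_experiment(small_samples, "lda", k=1, n_folds=5, seed=1,
                                max_train_pixels_per_sample=150)
        assert res.k == 1
        assert len(res.fold_metrics) == 5

    def test_separability_dial_is_monotone(self):
        """Mean Jaccard must not decrease across three increasing
        chromophore-contrast levels (one small inversion tolerated)."""
        jacs = []
        for mel, hem in ((1.05, 1.08), (1.25, 1.4), (1.8, 2.2)):
            base = sh.SceneConfig(height=40, width=40, melanin_multiplier=mel,
                                  hemoglobin_multiplier=hem)
            samples = sh.prepare_samples(sh.generate_dataset(5, base, seed=6))
            res = run_cv_experiment(samples, "mselect", k=2, n_folds=5, seed=2,
                                    max_train_pixels_per_sample=150)
            jacs.append(res.summary["jaccard"].mean)
        assert jacs[1] >= jacs[0] - 0.02
        assert jacs[2] >= jacs[1] - 0.02
        assert jacs[2] > jacs[0]

    def test_unknown_method_rejected(self, small_samples):
        with pytest.raises(ValueError, match="unknown method"):
            run_cv_experiment(small_samples, "nope", k=2)


class TestSweepDimensions:
    def test_one_row_per_k(self, small_samples):
        table, best = sweep_dimensions(small_samples, "pca", [2, 5], n_folds=5,
                                       seed=1, max_train_pixels_per_sample=120)
        assert len(table) == 2
        assert best in (2, 5)

    def test_fixed_k_method_yields_single_row_with_notice(self, small_samples):
        with pytest.warns(UserWarning, match="fixed dimensionality"):
            table, best = sweep_dimensions(small_samples, "mselect", [5, 10],
                                           n_folds=5, seed=1,
                                           max_train_pixels_per_sample=120)
        assert len(table) == 1
        assert best == 2

    def test_duplicates_deduplicated_and_oversized_skipped(self, small_samples):
        with pytest.warns(UserWarning):
            table, _ = sweep_dimensions(small_samples, "pca", [2, 2, 1000],
                                        n_folds=5, seed=1,
                                        max_train_pixels_per_sample=120)
        assert list(table["k"]) == [2]
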