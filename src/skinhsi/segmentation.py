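"""Per-pixel SVM tumor-margin segmentation with sample-grouped CV.

The experimental protocol: spectra (or reduced features) are classified
pixel-by-pixel with an RBF-kernel soft-margin SVM whose margin-violation
budget is about 5% of the training pixels (nu-parameterization).  Cross
validation is five-fold and *grouped by sample* — every pixel of an HSI
sample lands in the same fold, so validation measures generalization to
unseen specimens rather than unseen pixels.  Per-sample-scope reducers are
fitted on each sample individually; dataset-scope reducers (LDA, PCA-LDA,
RFI, autoencoder) are fitted only on the training folds of each CV
iteration.  Multiscale variants train one classifier per scale and fuse the
per-pixel predictions by majority vote (ties go to non-tumor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dimred
from .core import ReflectanceCube, SignatureTable, flatten, unflatten
from .metrics import MetricSummary, confusion_counts, confusion_metrics, jaccard, summarize_folds
from .synthetic import SyntheticScene

__all__ = [
    "Sample", "ClassifierConfig", "FoldSplit", "SegmentationResult",
    "prepare_samples", "train_svm", "margin_violation_fraction",
    "grouped_kfold", "fuse_multiscale", "run_cv_experiment", "sweep_dimensions",
]

METRIC_NAMES = ("jaccard", "accuracy", "sensitivity", "specificity")


@dataclass
class Sample:
    """One labeled specimen: a masked reflectance cube plus its tumor mask."""

    cube: ReflectanceCube
    tumor_mask: np.ndarray
    sample_id: str

    def labeled_table(self) -> SignatureTable:
        table = flatten(self.cube)
        table.labels = self.tumor_mask[table.coords[:, 0], table.coords[:, 1]].astype(int)
        return table


def prepare_samples(scenes: list[SyntheticScene]) -> list[Sample]:
    """Normalize synthetic scenes into labeled samples."""
    return [
        Sample(
            cube=scene.to_reflectance_cube(),
            tumor_mask=scene.tumor_mask,
            sample_id=scene.sample_id,
        )
        for scene in scenes
    ]


@dataclass(frozen=True)
class ClassifierConfig:
    """RBF-SVM settings.

    ``outlier_fraction`` is the margin-violation budget (the nu parameter):
    at most about that fraction of training pixels may violate the margin.
    ``false_negative_penalty`` > 1 up-weights the tumor class.
    """

    kernel: str = "rbf"
    outlier_fraction: float = 0.05
    gamma: str | float = "scale"
    false_negative_penalty: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.outlier_fraction < 0.5):
            raise ValueError("outlier_fraction must lie in [0, 0.5)")


def train_svm(features: np.ndarray, labels: np.ndarray, config: ClassifierConfig | None = None):
    """Fit standardization + nu-SVM on training pixels.

    Features are z-scored with training statistics inside the returned
    pipeline, because reducer outputs arrive on wildly different scales and
    the RBF kernel is not scale-invariant.  Raises on single-class input.
    """
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import NuSVC

    config = config or ClassifierConfig()
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("training labels contain a single class")
    class_weight = None
    if config.false_negative_penalty != 1.0:
        class_weight = {0: 1.0, 1: float(config.false_negative_penalty)}
    clf = Pipeline([
        ("scale", StandardScaler()),
        ("svm", NuSVC(
            nu=max(config.outlier_fraction, 1e-4),
            kernel=config.kernel,
            gamma=config.gamma,
            class_weight=class_weight,
            random_state=config.seed,
        )),
    ])
    return clf.fit(np.asarray(features, dtype=float), labels)


def margin_violation_fraction(classifier, features: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of points on the wrong side of their class margin."""
    y = np.where(np.asarray(labels, dtype=int) > 0, 1.0, -1.0)
    f = classifier.decision_function(np.asarray(features, dtype=float))
    return float(np.mean(y * f < 1.0 - 1e-9))


@dataclass(frozen=True)
class FoldSplit:
    """Assignment of whole samples to folds."""

    fold_of: dict[str, int]
    n_folds: int

    def fold_samples(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_of.items() if f == fold]

    def train_samples(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_of.items() if f != fold]


def grouped_kfold(sample_ids: list[str], n_folds: int = 5, seed: int = 0) -> FoldSplit:
    """Shuffle samples by seed and deal them round-robin into folds.

    Every pixel of a sample inherits its sample's fold, so folds partition
    samples, never split them.
    """
    unique = sorted(dict.fromkeys(sample_ids))
    if len(unique) < n_folds:
        raise ValueError(f"{len(unique)} samples cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = [unique[i] for i in rng.permutation(len(unique))]
    return FoldSplit(
        fold_of={sid: i % n_folds for i, sid in enumerate(order)},
        n_folds=n_folds,
    )


def fuse_multiscale(per_scale_predictions: list[np.ndarray]) -> np.ndarray:
    """Per-pixel majority vote across scales; ties resolve to non-tumor."""
    if not per_scale_predictions:
        raise ValueError("no scale predictions to fuse")
    shape = np.asarray(per_scale_predictions[0]).shape
    for p in per_scale_predictions[1:]:
        if np.asarray(p).shape != shape:
            raise ValueError("scale predictions are misaligned")
    votes = np.sum([np.asarray(p, dtype=int) for p in per_scale_predictions], axis=0)
    return (2 * votes > len(per_scale_predictions)).astype(int)


# --- feature computation -------------------------------------------------


def _per_sample_features(
    sample: Sample, method: str, k: int, seed: int, scales: tuple[int, ...] | None
) -> np.ndarray | list[np.ndarray]:
    """Features for a per-sample-scope method, one row per tissue pixel.

    Multiscale methods return one feature block per scale.
    """
    table = sample.labeled_table()
    if method == "baseline":
        return table.spectra
    if method == "pca":
        return dimred.fit_pca(table, k).transform(table.spectra)
    if method == "fastica":
        return dimred.fit_ica(table, k, flavor="fast", seed=seed).transform(table.spectra)
    if method == "rica":
        return dimred.fit_ica(table, k, flavor="reconstruction", seed=seed).transform(table.spectra)
    if method == "mselect":
        return dimred.fit_mselect(table.band_grid).transform(table.spectra)
    if method == "clusterpca":
        n = dimred.METHODS[method].get("default_scale", 6)
        model = dimred.fit_cluster_pca(sample.cube, n=n, k=k, seed=seed)
        return model._fit_scores
    if method == "superpca":
        n = dimred.METHODS[method].get("default_scale", 20)
        model = dimred.fit_super_pca(sample.cube, n_superpixels=n, k=k, seed=seed)
        return model._fit_scores
    if method in ("mclusterpca", "msuperpca"):
        use = scales or dimred.METHODS[method]["default_scales"]
        kind = "cluster" if method == "mclusterpca" else "super"
        model = dimred.fit_multiscale(sample.cube, list(use), k=k, kind=kind, seed=seed)
        return [m._fit_scores for m in model.models]
    raise ValueError(f"'{method}' is not a per-sample method")


def _fit_dataset_reducer(method: str, train_table: SignatureTable, k: int, seed: int):
    if method == "lda":
        return dimred.fit_lda(train_table)
    if method == "pcalda":
        return dimred.fit_lda(train_table, via_pca=max(k, 2))
    if method == "rfi":
        return dimred.fit_rfi(train_table, k, seed=seed)
    if method == "ae":
        return dimred.fit_autoencoder(train_table, k, seed=seed)
    raise ValueError(f"'{method}' is not a dataset-scope method")


def _subsample(rng: np.random.Generator, n: int, limit: int | None) -> np.ndarray:
    if limit is None or n <= limit:
        return np.arange(n)
    return np.sort(rng.choice(n, size=limit, replace=False))


@dataclass
class SegmentationResult:
    """Cross-validated per-pixel segmentation outcome."""

    method: str
    k: int
    fold_metrics: pd.DataFrame
    summary: dict[str, MetricSummary]
    predictions: dict[str, np.ndarray] = field(default_factory=dict)


def run_cv_experiment(
    samples: list[Sample],
    method: str,
    k: int,
    config: ClassifierConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
    max_train_pixels_per_sample: int | None = 400,
    scales: tuple[int, ...] | None = None,
) -> SegmentationResult:
    """Grouped k-fold CV of one reducer + SVM combination.

    For each fold the reducer is fitted respecting its scope, the SVM is
    trained on (optionally subsampled) training-fold pixels, and every
    validation pixel is predicted.  Per-fold metrics are computed over the
    pooled validation pixels of that fold; per-sample prediction masks are
    collected from the fold in which each sample was validated.
    """
    if method not in dimred.METHODS:
        raise ValueError(f"unknown method '{method}'")
    info = dimred.METHODS[method]
    if info["fixed_k"] is not None:
        k = info["fixed_k"]
    config = config or ClassifierConfig()
    split = grouped_kfold([s.sample_id for s in samples], n_folds, seed)
    by_id = {s.sample_id: s for s in samples}
    tables = {s.sample_id: s.labeled_table() for s in samples}

    per_sample_feats: dict[str, np.ndarray | list[np.ndarray]] = {}
    if info["scope"] == "per-sample":
        for s in samples:
            per_sample_feats[s.sample_id] = _per_sample_features(s, method, k, seed, scales)

    rng = np.random.default_rng(seed)
    fold_rows = []
    predictions: dict[str, np.ndarray] = {}
    for fold in range(n_folds):
        train_ids = split.train_samples(fold)
        val_ids = split.fold_samples(fold)
        sub_idx = {
            sid: _subsample(rng, len(tables[sid]), max_train_pixels_per_sample)
            for sid in train_ids
        }
        y_train = np.concatenate([tables[sid].labels[sub_idx[sid]] for sid in train_ids])

        if info["scope"] == "dataset":
            train_table = SignatureTable(
                spectra=np.concatenate(
                    [tables[sid].spectra[sub_idx[sid]] for sid in train_ids]
                ),
                coords=np.concatenate(
                    [tables[sid].coords[sub_idx[sid]] for sid in train_ids]
                ),
                band_grid=samples[0].cube.band_grid,
                sample_ids=np.concatenate(
                    [tables[sid].sample_ids[sub_idx[sid]] for sid in train_ids]
                ),
                labels=y_train,
            )
            if method == "baseline":
                feats = {sid: tables[sid].spectra for sid in by_id}
            else:
                reducer = _fit_dataset_reducer(method, train_table, k, seed)
                feats = {sid: reducer.transform(tables[sid].spectra) for sid in by_id}
            blocks = {sid: [feats[sid]] for sid in by_id}
        elif info["kind"] == "multiscale":
            blocks = {sid: list(per_sample_feats[sid]) for sid in by_id}
        else:
            blocks = {sid: [per_sample_feats[sid]] for sid in by_id}

        n_scales = len(next(iter(blocks.values())))
        scale_preds: dict[str, list[np.ndarray]] = {sid: [] for sid in val_ids}
        for s_i in range(n_scales):
            X_train = np.concatenate(
                [blocks[sid][s_i][sub_idx[sid]] for sid in train_ids]
            )
            clf = train_svm(X_train, y_train, config)
            for sid in val_ids:
                scale_preds[sid].append(clf.predict(blocks[sid][s_i]))

        y_true_fold, y_pred_fold = [], []
        for sid in val_ids:
            fused = fuse_multiscale(scale_preds[sid])
            y_true_fold.append(tables[sid].labels)
            y_pred_fold.append(fused)
            sample = by_id[sid]
            predictions[sid] = unflatten(
                tables[sid], fused.astype(float), sample.cube.data.shape[:2]
            ).astype(bool)
        y_true = np.concatenate(y_true_fold)
        y_pred = np.concatenate(y_pred_fold)
        counts = confusion_counts(y_pred.astype(bool), y_true.astype(bool))
        row = {"fold": fold, "jaccard": jaccard(y_pred.astype(bool), y_true.astype(bool))}
        row.update(confusion_metrics(counts))
        fold_rows.append(row)

    fold_metrics = pd.DataFrame(fold_rows)
    summary = {
        m: summarize_folds(fold_metrics[m].dropna().to_numpy())
        for m in METRIC_NAMES
        if fold_metrics[m].notna().any()
    }
    return SegmentationResult(
        method=method, k=k, fold_metrics=fold_metrics, summary=summary,
        predictions=predictions,
    )


def sweep_dimensions(
    samples: list[Sample],
    method: str,
    k_set: list[int],
    config: ClassifierConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
    max_train_pixels_per_sample: int | None = 400,
) -> tuple[pd.DataFrame, int]:
    """One CV experiment per retained-dimension count.

    Returns the per-k summary table and the best k by mean Jaccard (ties
    resolve toward the smaller, cheaper model).  Methods with a fixed output
    dimensionality yield a single row at that k, with a notice.
    """
    info = dimred.METHODS.get(method)
    if info is None:
        raise ValueError(f"unknown method '{method}'")
    n_bands = len(samples[0].cube.band_grid)
    if info["fixed_k"] is not None:
        warnings.warn(
            f"method '{method}' has a fixed dimensionality of {info['fixed_k']}; "
            "ignoring the requested sweep values", UserWarning, stacklevel=2,
        )
        ks = [info["fixed_k"]]
    else:
        ks = list(dict.fromkeys(int(k) for k in k_set))
        if len(ks) < len(k_set):
            warnings.warn("duplicate k values removed", UserWarning, stacklevel=2)
        kept = [k for k in ks if k <= n_bands]
        for k in ks:
            if k > n_bands:
                warnings.warn(f"k={k} exceeds the {n_bands} bands; skipped",
                              UserWarning, stacklevel=2)
        ks = kept
    rows = []
    for k in ks:
        res = run_cv_experiment(
            samples, method, k, config=config, n_folds=n_folds, seed=seed,
            max_train_pixels_per_sample=max_train_pixels_per_sample,
        )
        row = {"method": method, "k": res.k}
        for m, s in res.summary.items():
            row[f"{m}_mean"] = s.mean
            row[f"{m}_sem"] = s.sem
        rows.append(row)
    table = pd.DataFrame(rows)
    best = table.sort_values(["jaccard_mean", "k"], ascending=[False, True]).iloc[0]
    return table, int(best["k"])
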