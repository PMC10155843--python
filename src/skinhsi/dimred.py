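"""Dimension reduction schemes for skin HSI spectra.

Eleven reducers sit behind one fit/transform contract: the unsupervised
feature extractors PCA, FastICA, reconstruction ICA (RICA), a shallow
autoencoder, SuperPCA and cluster-wise PCA (ClusterPCA) with their
multiscale voting variants; the supervised LDA (optionally PCA-denoised,
PCA-LDA) and random-forest-importance band selection (RFI); and manual band
selection (MSelect) at the hemoglobin and melanin marker wavelengths.

ClusterPCA is the centerpiece: instead of spatially contiguous superpixels
it groups pixels by *spectral* similarity — N-FINDR endmembers define the
clusters, each pixel joins its minimum-SAM-angle endmember, PCA is trained
separately per cluster, and each pixel keeps the top-k scores of its own
cluster, re-imaged onto the cube geometry.

All reducers expose exactly ``k`` output columns (multiscale models expose
one k-column block per scale) and are deterministic under a fixed seed.
"""

from __future__ import annotations

import abc
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .core import BandGrid, ReflectanceCube, SignatureTable, flatten, unflatten
from .unmixing import EndmemberSet, assign_clusters, nfindr, sam, sam_matrix

__all__ = [
    "DimRedModel", "PCAModel", "MSelectModel", "LDAModel", "RFIModel",
    "FastICAModel", "RICAModel", "AutoencoderModel",
    "ClusterPCAModel", "SuperPCAModel", "MultiscaleModel",
    "fit_pca", "fit_mselect", "fit_lda", "fit_rfi", "fit_ica",
    "fit_autoencoder", "fit_cluster_pca", "fit_super_pca", "fit_multiscale",
    "METHODS",
]

#: Marker wavelengths for manual band selection: an hemoglobin absorption
#: band (540 nm) and a melanin-dominated red band (650 nm).
MSELECT_TARGETS_NM = (540.0, 650.0)


class DimRedModel(abc.ABC):
    """A fitted reducer mapping spectra to a ``k``-column feature space."""

    method: str
    k: int
    scope: str  # "per-sample" or "dataset"
    band_grid: BandGrid

    @abc.abstractmethod
    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project ``(n, n_bands)`` spectra to ``(n, k)`` features."""


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| element positive."""
    out = components.copy()
    for i in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[i])))
        if out[i, j] < 0:
            out[i] = -out[i]
    return out


@dataclass
class PCAModel(DimRedModel):
    """Mean-centered PCA via eigendecomposition of the band covariance.

    Components are ordered by descending eigenvalue and sign-fixed so the
    largest-magnitude loading of each component is positive, which makes
    scores exactly reproducible across implementations.
    """

    k: int
    band_grid: BandGrid
    scope: str = "per-sample"
    method: str = "pca"
    mean_: np.ndarray | None = None
    components_: np.ndarray | None = None   # (k, n_bands)
    explained_variance_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "PCAModel":
        X = np.asarray(X, dtype=float)
        n, b = X.shape
        if self.k > b:
            raise ValueError(f"k={self.k} exceeds the {b} available bands")
        if n <= self.k:
            raise ValueError("need more pixels than retained dimensions")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        cov = (Xc.T @ Xc) / (n - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][: self.k]
        self.explained_variance_ = np.clip(evals[order], 0.0, None)
        self.components_ = _fix_signs(evecs[:, order].T)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.components_ is None:
            raise RuntimeError("model is not fitted")
        return (np.asarray(X, dtype=float) - self.mean_) @ self.components_.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return scores @ self.components_ + self.mean_


def fit_pca(table: SignatureTable, k: int, scope: str = "per-sample") -> PCAModel:
    model = PCAModel(k=k, band_grid=table.band_grid, scope=scope)
    return model.fit(table.spectra)


@dataclass
class MSelectModel(DimRedModel):
    """Manual selection of the two chromophore marker bands; k is fixed at 2."""

    band_grid: BandGrid
    targets_nm: tuple[float, ...] = MSELECT_TARGETS_NM
    method: str = "mselect"
    scope: str = "per-sample"
    band_indices: np.ndarray | None = None
    k: int = 2

    def fit(self) -> "MSelectModel":
        w = self.band_grid.wavelengths
        for t in self.targets_nm:
            if not (w[0] <= t <= w[-1]):
                raise ValueError(f"target wavelength {t:g} nm outside the band grid")
        self.band_indices = np.array([self.band_grid.nearest(t) for t in self.targets_nm])
        self.k = len(self.targets_nm)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float)[:, self.band_indices]


def fit_mselect(band_grid: BandGrid) -> MSelectModel:
    return MSelectModel(band_grid=band_grid).fit()


@dataclass
class LDAModel(DimRedModel):
    """Fisher linear discriminant; one projection axis for a binary problem.

    With ``via_pca=m`` the spectra are first denoised by keeping ``m`` PCA
    components (PCA-LDA), which also regularizes the within-class scatter.
    """

    band_grid: BandGrid
    via_pca: int | None = None
    method: str = "lda"
    scope: str = "dataset"
    k: int = 1
    _pca: PCAModel | None = None
    _lda: object = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LDAModel":
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("LDA here expects exactly two classes")
        Z = X
        if self.via_pca is not None:
            if self.via_pca < 2:
                raise ValueError("via_pca must keep at least 2 components")
            self.method = "pcalda"
            self._pca = PCAModel(k=self.via_pca, band_grid=self.band_grid).fit(X)
            Z = self._pca.transform(X)
        else:
            sw = np.zeros((Z.shape[1], Z.shape[1]))
            for c in classes:
                Zc = Z[y == c]
                if Zc.shape[0] > 1:
                    sw += (Zc.shape[0] - 1) * np.cov(Zc, rowvar=False)
            evals = np.linalg.eigvalsh(sw)
            if evals[-1] <= 0 or evals[0] / evals[-1] < 1e-10:
                raise ValueError(
                    "within-class scatter is singular; denoise first with "
                    "PCA-LDA (via_pca=m)"
                )
        self._lda = LinearDiscriminantAnalysis(solver="svd", n_components=1).fit(Z, y)
        self.k = 1
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self._lda is None:
            raise RuntimeError("model is not fitted")
        Z = np.asarray(X, dtype=float)
        if self._pca is not None:
            Z = self._pca.transform(Z)
        return self._lda.transform(Z)


def fit_lda(table: SignatureTable, via_pca: int | None = None) -> LDAModel:
    if table.labels is None:
        raise ValueError("LDA needs a labeled table")
    model = LDAModel(band_grid=table.band_grid, via_pca=via_pca)
    return model.fit(table.spectra, table.labels)


@dataclass
class RFIModel(DimRedModel):
    """Band selection by boosted-tree feature importance.

    An AdaBoost ensemble of depth-limited trees (Gini impurity splits) is
    trained on the labeled spectra; every wavelength receives an importance
    weight and the ``k`` most important bands are retained, ties broken
    toward the lower wavelength.
    """

    k: int
    band_grid: BandGrid
    n_estimators: int = 100
    max_depth: int = 3
    seed: int = 0
    method: str = "rfi"
    scope: str = "dataset"
    importances_: np.ndarray | None = None
    band_indices: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RFIModel":
        from sklearn.ensemble import AdaBoostClassifier
        from sklearn.tree import DecisionTreeClassifier

        X = np.asarray(X, dtype=float)
        b = X.shape[1]
        if self.k > b:
            raise ValueError(f"k={self.k} exceeds the {b} available bands")
        ensemble = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(
                max_depth=self.max_depth, criterion="gini", random_state=self.seed
            ),
            n_estimators=self.n_estimators,
            random_state=self.seed,
        ).fit(X, np.asarray(y, dtype=int))
        self.importances_ = ensemble.feature_importances_
        # stable selection: highest importance first, ties -> lower wavelength
        order = np.lexsort((np.arange(b), -self.importances_))
        self.band_indices = np.sort(order[: self.k])
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.band_indices is None:
            raise RuntimeError("model is not fitted")
        return np.asarray(X, dtype=float)[:, self.band_indices]


def fit_rfi(
    table: SignatureTable, k: int, n_estimators: int = 100, max_depth: int = 3,
    seed: int = 0,
) -> RFIModel:
    if table.labels is None:
        raise ValueError("RFI needs a labeled table")
    model = RFIModel(k=k, band_grid=table.band_grid, n_estimators=n_estimators,
                     max_depth=max_depth, seed=seed)
    return model.fit(table.spectra, table.labels)


@dataclass
class FastICAModel(DimRedModel):
    """FastICA components (delegates to scikit-learn's implementation)."""

    k: int
    band_grid: BandGrid
    seed: int = 0
    method: str = "fastica"
    scope: str = "per-sample"
    converged: bool = True
    _ica: object = None

    def fit(self, X: np.ndarray) -> "FastICAModel":
        from sklearn.decomposition import FastICA
        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            self._ica = FastICA(
                n_components=self.k, random_state=self.seed,
                whiten="unit-variance", max_iter=500,
            ).fit(np.asarray(X, dtype=float))
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            self.converged = False
            warnings.warn("FastICA did not converge; returning the partial result",
                          RuntimeWarning, stacklevel=2)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self._ica.transform(np.asarray(X, dtype=float))


@dataclass
class RICAModel(DimRedModel):
    """Reconstruction ICA: tied-weight linear features with a sparsity cost.

    Minimizes ``||X W^T W - X||^2 / n + lam/n * sum smooth_l1(X W^T)`` over
    an unconstrained ``k x n_bands`` filter matrix with L-BFGS, on
    standardized spectra.  Unlike FastICA this handles overcomplete bases
    and never needs an orthogonality constraint.
    """

    k: int
    band_grid: BandGrid
    seed: int = 0
    lam: float = 0.5
    max_iter: int = 200
    method: str = "rica"
    scope: str = "per-sample"
    converged: bool = True
    W_: np.ndarray | None = None
    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "RICAModel":
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        Z = (X - self.mean_) / self.scale_
        rng = np.random.default_rng(self.seed)
        W0 = rng.standard_normal((self.k, d)) / np.sqrt(d)
        eps = 1e-8

        def objective(w_flat: np.ndarray) -> tuple[float, np.ndarray]:
            W = w_flat.reshape(self.k, d)
            H = Z @ W.T                     # (n, k) latent responses
            R = H @ W - Z                   # reconstruction residual
            g = np.sqrt(H * H + eps)
            loss = (R * R).sum() / n + self.lam * g.sum() / n
            grad = (2.0 / n) * W @ (R.T @ Z + Z.T @ R) + (self.lam / n) * (H / g).T @ Z
            return loss, grad.ravel()

        res = minimize(objective, W0.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": self.max_iter})
        self.converged = bool(res.success)
        if not self.converged:
            warnings.warn("RICA optimizer stopped early; returning the partial result",
                          RuntimeWarning, stacklevel=2)
        self.W_ = res.x.reshape(self.k, d)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.W_ is None:
            raise RuntimeError("model is not fitted")
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return Z @ self.W_.T


def fit_ica(table: SignatureTable, k: int, flavor: str = "fast", seed: int = 0):
    """Fit FastICA (``flavor='fast'``) or reconstruction ICA (``'reconstruction'``)."""
    if table.spectra.shape[0] <= k:
        raise ValueError("need more pixels than components")
    if flavor == "fast":
        return FastICAModel(k=k, band_grid=table.band_grid, seed=seed).fit(table.spectra)
    if flavor in ("reconstruction", "rica"):
        return RICAModel(k=k, band_grid=table.band_grid, seed=seed).fit(table.spectra)
    raise ValueError(f"unknown ICA flavor '{flavor}'")


@dataclass
class AutoencoderModel(DimRedModel):
    """Shallow autoencoder: one hidden layer of ``k`` units trained to
    reproduce its input; the hidden activations are the features.

    Spectra are standardized internally; ``reconstruction_mse_`` is reported
    in that standardized space.
    """

    k: int
    band_grid: BandGrid
    seed: int = 0
    activation: str = "logistic"
    max_iter: int = 500
    method: str = "ae"
    scope: str = "dataset"
    reconstruction_mse_: float | None = None
    _net: object = None
    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "AutoencoderModel":
        from sklearn.neural_network import MLPRegressor

        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        Z = (X - self.mean_) / self.scale_
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._net = MLPRegressor(
                hidden_layer_sizes=(self.k,), activation=self.activation,
                solver="lbfgs", max_iter=self.max_iter, random_state=self.seed,
            ).fit(Z, Z)
        recon = self._net.predict(Z)
        self.reconstruction_mse_ = float(np.mean((recon - Z) ** 2))
        return self

    def _encode(self, Z: np.ndarray) -> np.ndarray:
        H = Z @ self._net.coefs_[0] + self._net.intercepts_[0]
        if self.activation == "logistic":
            return 1.0 / (1.0 + np.exp(-H))
        if self.activation == "tanh":
            return np.tanh(H)
        if self.activation == "relu":
            return np.maximum(H, 0.0)
        return H  # identity

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self._net is None:
            raise RuntimeError("model is not fitted")
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return self._encode(Z)


def fit_autoencoder(
    table: SignatureTable, k: int, seed: int = 0, activation: str = "logistic",
    max_iter: int = 500,
) -> AutoencoderModel:
    if table.spectra.shape[0] <= k:
        raise ValueError("need more pixels than hidden units")
    return AutoencoderModel(
        k=k, band_grid=table.band_grid, seed=seed, activation=activation,
        max_iter=max_iter,
    ).fit(table.spectra)


# --- spatial reducers ----------------------------------------------------


def _per_cluster_scores(
    X: np.ndarray, labels: np.ndarray, k: int, band_grid: BandGrid
) -> tuple[dict[int, PCAModel], np.ndarray]:
    """Fit one PCA per cluster and score each pixel with its own cluster.

    Per-cluster dimensionality is capped at ``min(k, cluster_size - 1)``
    and zero-padded back to ``k`` so every pixel exposes the same width.
    """
    scores = np.zeros((X.shape[0], k))
    models: dict[int, PCAModel] = {}
    for lab in np.unique(labels):
        idx = np.nonzero(labels == lab)[0]
        k_c = min(k, idx.size - 1, X.shape[1])
        if k_c < 1:
            continue
        m = PCAModel(k=k_c, band_grid=band_grid).fit(X[idx])
        models[int(lab)] = m
        scores[idx, :k_c] = m.transform(X[idx])
    return models, scores


def _merge_small_clusters(
    labels: np.ndarray, endmembers: EndmemberSet, min_size: int = 2
) -> np.ndarray:
    """Reassign pixels of clusters smaller than ``min_size`` to the cluster
    of the nearest endmember (by SAM between endmember spectra)."""
    labels = labels.copy()
    counts = np.bincount(labels, minlength=endmembers.n)
    big = np.nonzero(counts >= min_size)[0]
    if big.size == 0:
        return np.zeros_like(labels)
    for lab in np.nonzero((counts > 0) & (counts < min_size))[0]:
        dists = [sam(endmembers.spectra[lab], endmembers.spectra[j]) for j in big]
        labels[labels == lab] = big[int(np.argmin(dists))]
    return labels


@dataclass
class ClusterPCAModel(DimRedModel):
    """Cluster-wise PCA: SAM clusters around N-FINDR endmembers, PCA per
    cluster, scores re-imaged onto the cube geometry.

    ``n=1`` bypasses unmixing entirely and reduces exactly to per-sample
    PCA.  Empty clusters are dropped; clusters with fewer than two pixels
    are merged into the cluster of the spectrally nearest endmember.
    """

    n: int
    k: int
    band_grid: BandGrid
    seed: int = 0
    method: str = "clusterpca"
    scope: str = "per-sample"
    endmembers: EndmemberSet | None = None
    cluster_models: dict[int, PCAModel] = field(default_factory=dict)
    _fit_shape: tuple[int, int] | None = None
    _fit_scores: np.ndarray | None = None
    _fit_table: SignatureTable | None = None

    def fit(self, cube: ReflectanceCube) -> "ClusterPCAModel":
        if self.n < 1:
            raise ValueError("need at least one cluster")
        table = flatten(cube)
        X = table.spectra
        if self.n == 1:
            labels = np.zeros(X.shape[0], dtype=int)
        else:
            self.endmembers = nfindr(table, self.n, seed=self.seed)
            labels = assign_clusters(table, self.endmembers).labels
            labels = _merge_small_clusters(labels, self.endmembers)
        self.cluster_models, scores = _per_cluster_scores(X, labels, self.k, self.band_grid)
        self._fit_shape = cube.data.shape[:2]
        self._fit_scores = scores
        self._fit_table = table
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Score arbitrary spectra: assign to a cluster by SAM, then project."""
        X = np.asarray(X, dtype=float)
        scores = np.zeros((X.shape[0], self.k))
        if self.endmembers is None:
            labels = np.zeros(X.shape[0], dtype=int)
        else:
            ang = sam_matrix(X, self.endmembers.spectra)
            fitted = np.array(sorted(self.cluster_models))
            labels = fitted[np.argmin(ang[:, fitted], axis=1)]
        for lab, m in self.cluster_models.items():
            idx = np.nonzero(labels == lab)[0]
            if idx.size:
                scores[idx, : m.k] = m.transform(X[idx])
        return scores

    def score_stack(self) -> np.ndarray:
        """Fitted-sample scores aligned spatially: ``(rows, cols, k)``."""
        if self._fit_scores is None:
            raise RuntimeError("model is not fitted")
        return unflatten(self._fit_table, self._fit_scores, self._fit_shape)


def fit_cluster_pca(cube: ReflectanceCube, n: int, k: int, seed: int = 0) -> ClusterPCAModel:
    return ClusterPCAModel(n=n, k=k, band_grid=cube.band_grid, seed=seed).fit(cube)


@dataclass
class SuperPCAModel(DimRedModel):
    """Superpixel-wise PCA.

    The tissue region is oversegmented with SLIC on the first three global
    PCA score channels; PCA is then trained per superpixel exactly as in
    cluster-wise PCA.  One superpixel reduces to per-sample PCA.
    """

    n_superpixels: int
    k: int
    band_grid: BandGrid
    seed: int = 0
    compactness: float = 10.0
    method: str = "superpca"
    scope: str = "per-sample"
    segment_labels_: np.ndarray | None = None   # (rows, cols), -1 off-tissue
    segment_models: dict[int, PCAModel] = field(default_factory=dict)
    _fit_shape: tuple[int, int] | None = None
    _fit_scores: np.ndarray | None = None
    _fit_table: SignatureTable | None = None

    def fit(self, cube: ReflectanceCube) -> "SuperPCAModel":
        from skimage.segmentation import slic

        if self.n_superpixels < 1:
            raise ValueError("need at least one superpixel")
        table = flatten(cube)
        X = table.spectra
        h, w = cube.data.shape[:2]
        if self.n_superpixels == 1:
            seg = np.where(cube.tissue_mask, 1, 0)
        else:
            base = PCAModel(k=min(3, X.shape[1]), band_grid=self.band_grid).fit(X)
            chan = unflatten(table, base.transform(X), (h, w))
            lo = chan.reshape(-1, chan.shape[-1]).min(axis=0)
            hi = chan.reshape(-1, chan.shape[-1]).max(axis=0)
            chan = (chan - lo) / np.where(hi > lo, hi - lo, 1.0)
            seg = slic(
                chan, n_segments=self.n_superpixels, compactness=self.compactness,
                mask=cube.tissue_mask, start_label=1, channel_axis=-1,
            )
        self.segment_labels_ = np.where(cube.tissue_mask, seg, -1)
        labels = self.segment_labels_[table.coords[:, 0], table.coords[:, 1]]
        # fold sub-minimal segments into the spectrally nearest neighbor
        uniq, counts = np.unique(labels, return_counts=True)
        big = uniq[counts >= 2]
        if big.size == 0:
            labels = np.full_like(labels, int(uniq[0]))
        else:
            means = {int(u): X[labels == u].mean(axis=0) for u in uniq}
            for u in uniq[counts < 2]:
                d = [sam(means[int(u)], means[int(v)]) for v in big]
                tgt = int(big[int(np.argmin(d))])
                self.segment_labels_[self.segment_labels_ == u] = tgt
                labels[labels == u] = tgt
        self.segment_models, scores = _per_cluster_scores(X, labels, self.k, self.band_grid)
        self._fit_shape = (h, w)
        self._fit_scores = scores
        self._fit_table = table
        return self

    @property
    def achieved_superpixels(self) -> int:
        return len(self.segment_models)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Score spectra of the *fitted* geometry (row order of the fit table)."""
        X = np.asarray(X, dtype=float)
        if self._fit_table is None:
            raise RuntimeError("model is not fitted")
        if X.shape[0] != len(self._fit_table):
            raise ValueError("SuperPCA transform expects the fitted sample's pixels")
        labels = self.segment_labels_[
            self._fit_table.coords[:, 0], self._fit_table.coords[:, 1]
        ]
        scores = np.zeros((X.shape[0], self.k))
        for lab, m in self.segment_models.items():
            idx = np.nonzero(labels == lab)[0]
            if idx.size:
                scores[idx, : m.k] = m.transform(X[idx])
        return scores

    def score_stack(self) -> np.ndarray:
        if self._fit_scores is None:
            raise RuntimeError("model is not fitted")
        return unflatten(self._fit_table, self._fit_scores, self._fit_shape)


def fit_super_pca(
    cube: ReflectanceCube, n_superpixels: int, k: int, seed: int = 0
) -> SuperPCAModel:
    return SuperPCAModel(
        n_superpixels=n_superpixels, k=k, band_grid=cube.band_grid, seed=seed
    ).fit(cube)


@dataclass
class MultiscaleModel:
    """One spatial reducer per scale; classification fusion happens later.

    ``kind`` selects cluster-wise (``"cluster"``) or superpixel (``"super"``)
    PCA; ``transform`` style access goes through :meth:`score_stacks`, which
    returns one ``(rows, cols, k)`` block per scale.
    """

    scales: tuple[int, ...]
    k: int
    kind: str
    models: list[DimRedModel]
    method: str = "multiscale"
    scope: str = "per-sample"

    def score_stacks(self) -> list[np.ndarray]:
        return [m.score_stack() for m in self.models]


def fit_multiscale(
    cube: ReflectanceCube, scales: list[int], k: int, kind: str = "cluster",
    seed: int = 0,
) -> MultiscaleModel:
    """Fit one cluster-wise or superpixel PCA per scale.

    Duplicate scales are dropped (order-preserving) with a warning.
    """
    if kind not in ("cluster", "super"):
        raise ValueError("kind must be 'cluster' or 'super'")
    if len(scales) < 1:
        raise ValueError("need at least one scale")
    deduped = list(dict.fromkeys(int(s) for s in scales))
    if len(deduped) < len(scales):
        warnings.warn("duplicate scales removed", UserWarning, stacklevel=2)
    if kind == "cluster":
        models = [fit_cluster_pca(cube, n=s, k=k, seed=seed) for s in deduped]
    else:
        models = [fit_super_pca(cube, n_superpixels=s, k=k, seed=seed) for s in deduped]
    return MultiscaleModel(
        scales=tuple(deduped), k=k, kind=kind, models=models,
        method="mclusterpca" if kind == "cluster" else "msuperpca",
    )


def has_twin_peak_signature(
    component: np.ndarray,
    band_grid: BandGrid,
    peaks_nm: tuple[float, float] = (542.0, 576.0),
    tol_nm: float = 6.0,
    smooth: int = 5,
) -> bool:
    """Does a loading vector carry the oxygenated-hemoglobin twin peaks?

    The HbO2 extinction curve has alpha/beta bands at 576 and 542 nm with a
    valley near 560 nm; an eigenvector that compresses the hemoglobin
    component inherits that shape.  The test: after light smoothing, the
    component restricted to 515-605 nm must show a *clean* peak-valley-peak
    pattern — local extrema within ``tol_nm`` of both peak wavelengths,
    deflecting in the same direction, with an opposite-direction extremum in
    between, and no more than five interior extrema in the whole window
    (noise-dominated loadings wiggle far more).
    """
    w = band_grid.wavelengths
    v = np.asarray(component, dtype=float)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        v = np.convolve(v, kernel, mode="same")
    window = (w >= 515.0) & (w <= 605.0)
    wi, vi = w[window], v[window]
    d2 = np.diff(np.sign(np.diff(vi)))
    n_extrema = int(np.count_nonzero(d2))
    if n_extrema > 5:
        return False
    maxima = wi[np.where(d2 < 0)[0] + 1]
    minima = wi[np.where(d2 > 0)[0] + 1]
    lo, hi = sorted(peaks_nm)
    for same, other in ((maxima, minima), (minima, maxima)):
        hit_lo = same[np.abs(same - lo) <= tol_nm]
        hit_hi = same[np.abs(same - hi) <= tol_nm]
        if hit_lo.size and hit_hi.size:
            between = other[(other > hit_lo.max()) & (other < hit_hi.min())]
            if between.size:
                return True
    return False


#: Method registry: how the segmentation module should drive each reducer.
#: ``scope`` follows the experimental protocol — every reducer is trained
#: per sample except LDA, RFI and the autoencoder, which see the (training
#: portion of the) whole dataset.  ``fixed_k`` marks methods whose output
#: dimensionality is not adjustable.
METHODS: dict[str, dict] = {
    "baseline":    {"kind": "identity", "scope": "per-sample", "supervised": False, "fixed_k": None},
    "pca":         {"kind": "table",    "scope": "per-sample", "supervised": False, "fixed_k": None},
    "fastica":     {"kind": "table",    "scope": "per-sample", "supervised": False, "fixed_k": None},
    "rica":        {"kind": "table",    "scope": "per-sample", "supervised": False, "fixed_k": None},
    "mselect":     {"kind": "table",    "scope": "per-sample", "supervised": False, "fixed_k": 2},
    "lda":         {"kind": "table",    "scope": "dataset",    "supervised": True,  "fixed_k": 1},
    "pcalda":      {"kind": "table",    "scope": "dataset",    "supervised": True,  "fixed_k": 1},
    "ae":          {"kind": "table",    "scope": "dataset",    "supervised": False, "fixed_k": None},
    "rfi":         {"kind": "table",    "scope": "dataset",    "supervised": True,  "fixed_k": None},
    "clusterpca":  {"kind": "spatial",  "scope": "per-sample", "supervised": False, "fixed_k": None,
                    "default_scale": 6},
    "superpca":    {"kind": "spatial",  "scope": "per-sample", "supervised": False, "fixed_k": None,
                    "default_scale": 20},
    "mclusterpca": {"kind": "multiscale", "scope": "per-sample", "supervised": False, "fixed_k": None,
                    "default_scales": (2, 5, 6, 8, 10)},
    "msuperpca":   {"kind": "multiscale", "scope": "per-sample", "supervised": False, "fixed_k": None,
                    "default_scales": (9, 14, 20, 28, 40)},
}
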