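"""Endmember extraction and spectral-angle clustering.

These are the spectral building blocks of cluster-wise PCA: N-FINDR picks
``n`` "pure" pixels (endmembers) as the vertices of the maximum-volume
simplex the pixel cloud supports, and every pixel is then assigned to the
cluster of its most similar endmember under the spectral angle mapper
(SAM).  SAM measures the angle between two spectra viewed as vectors, so it
is invariant to positive scaling (illumination intensity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SignatureTable

__all__ = ["EndmemberSet", "ClusterAssignment", "sam", "sam_matrix", "nfindr",
           "assign_clusters"]


@dataclass
class EndmemberSet:
    """Endmember spectra and the pixel row each one came from."""

    spectra: np.ndarray       # (n, n_bands)
    pixel_indices: np.ndarray  # (n,) row indices into the source table

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.pixel_indices = np.asarray(self.pixel_indices, dtype=int)
        if self.spectra.ndim != 2 or self.spectra.shape[0] < 2:
            raise ValueError("need at least two endmembers")
        if self.pixel_indices.shape != (self.spectra.shape[0],):
            raise ValueError("one pixel index per endmember required")

    @property
    def n(self) -> int:
        return int(self.spectra.shape[0])


@dataclass
class ClusterAssignment:
    """Per-pixel cluster labels and the full pixel-by-endmember angle matrix.

    ``labels[p] == argmin_i angles[p, i]`` with ties broken toward the lower
    endmember index; ``n_fallback`` counts zero-norm pixels that were
    assigned to cluster 0 because SAM is undefined for them.
    """

    labels: np.ndarray
    angles: np.ndarray
    n_fallback: int = 0


def sam(a: np.ndarray, b: np.ndarray) -> float:
    """Spectral angle between two spectra, in radians.

    ``arccos(<a, b> / (||a|| ||b||))`` clamped to [0, pi]; nonnegative
    spectra always land in [0, pi/2].
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("spectra must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("SAM is undefined for a zero spectrum")
    return float(np.arccos(np.clip(a @ b / (na * nb), -1.0, 1.0)))


def sam_matrix(spectra: np.ndarray, references: np.ndarray) -> np.ndarray:
    """Pairwise spectral angles, shape ``(n_spectra, n_references)``.

    Zero-norm rows yield ``pi/2`` against every reference (maximally
    dissimilar) rather than an error; callers decide how to treat them.
    """
    X = np.asarray(spectra, dtype=float)
    R = np.asarray(references, dtype=float)
    xn = np.linalg.norm(X, axis=1)
    rn = np.linalg.norm(R, axis=1)
    if np.any(rn == 0):
        raise ValueError("reference spectra must be nonzero")
    safe_xn = np.where(xn == 0, 1.0, xn)
    cos = (X / safe_xn[:, None]) @ (R / rn[:, None]).T
    ang = np.arccos(np.clip(cos, -1.0, 1.0))
    ang[xn == 0, :] = np.pi / 2
    return ang


def _simplex_dets(projected: np.ndarray, vertex_idx: np.ndarray) -> float:
    """|det| volume measure of the simplex spanned by the chosen vertices."""
    V = projected[vertex_idx]
    return float(abs(np.linalg.det(V[1:] - V[0])))


def nfindr(
    table: SignatureTable, n: int, seed: int = 0, max_sweeps: int = 50
) -> EndmemberSet:
    """N-FINDR endmember extraction.

    Spectra are projected to ``n - 1`` dimensions by PCA, a simplex is
    seeded with ``n`` random distinct pixels, and full replacement sweeps
    follow: each vertex in turn is swapped for whichever pixel most
    increases the simplex ``|det|`` volume, until a sweep makes no change
    (or ``max_sweeps`` is hit).  Endmembers are always actual input pixels.
    """
    X = table.spectra
    p = X.shape[0]
    if n < 2:
        raise ValueError("need at least two endmembers")
    if p <= n:
        raise ValueError("need more pixels than endmembers")
    distinct = np.unique(X, axis=0)
    if distinct.shape[0] < n:
        raise ValueError(
            f"only {distinct.shape[0]} distinct spectra for {n} endmembers"
        )

    # PCA projection to n-1 dims (economy SVD on the centered matrix).
    mean = X.mean(axis=0)
    _, _, vt = np.linalg.svd(X - mean, full_matrices=False)
    Y = (X - mean) @ vt[: n - 1].T

    rng = np.random.default_rng(seed)
    order = rng.permutation(p)
    chosen: list[int] = []
    seen: set[bytes] = set()
    for idx in order:
        key = X[idx].tobytes()
        if key not in seen:
            seen.add(key)
            chosen.append(int(idx))
        if len(chosen) == n:
            break
    vertices = np.array(chosen)
    volume = _simplex_dets(Y, vertices)

    for _ in range(max_sweeps):
        changed = False
        for j in range(n):
            # det is evaluated for every candidate pixel in vertex slot j
            V = Y[vertices]
            trial = np.broadcast_to(V, (p, n, n - 1)).copy()
            trial[:, j, :] = Y
            vols = np.abs(np.linalg.det(trial[:, 1:, :] - trial[:, :1, :]))
            best = int(np.argmax(vols))
            if vols[best] > volume * (1 + 1e-12) and best not in vertices:
                vertices[j] = best
                volume = float(vols[best])
                changed = True
        if not changed:
            break

    return EndmemberSet(spectra=X[vertices].copy(), pixel_indices=vertices)


def assign_clusters(table: SignatureTable, endmembers: EndmemberSet) -> ClusterAssignment:
    """Label each pixel with its most similar endmember (minimum SAM angle).

    Ties break toward the lower endmember index.  Zero-norm pixels fall back
    to cluster 0 and are counted in ``n_fallback``.
    """
    if table.n_bands != endmembers.spectra.shape[1]:
        raise ValueError("band counts of table and endmembers differ")
    angles = sam_matrix(table.spectra, endmembers.spectra)
    labels = np.argmin(angles, axis=1)
    zero_rows = np.linalg.norm(table.spectra, axis=1) == 0
    labels[zero_rows] = 0
    return ClusterAssignment(
        labels=labels.astype(int),
        angles=angles,
        n_fallback=int(zero_rows.sum()),
    )
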