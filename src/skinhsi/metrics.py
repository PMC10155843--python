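"""Segmentation evaluation: Jaccard coefficient, confusion-matrix metrics,
fold aggregation, and report rendering.

The tumor class is the positive class throughout.  Cross-validated metrics
are presented as mean with the standard error of the mean (SEM) across
folds, using the sample (n-1) standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts", "MetricSummary",
    "jaccard", "confusion_counts", "confusion_metrics", "summarize_folds",
    "render_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel counts with tumor as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSummary:
    """Mean and SEM of a per-fold metric."""

    mean: float
    sem: float | None
    n_folds: int


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def jaccard(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Jaccard coefficient |A n B| / |A u B| over positive (tumor) pixels.

    When neither mask contains a positive pixel the union is empty and the
    coefficient is defined as 1 (perfect agreement on "no tumor"), with a
    warning.
    """
    a, b = _as_bool(pred_mask), _as_bool(true_mask)
    if a.shape != b.shape:
        raise ValueError("masks are not aligned")
    union = np.count_nonzero(a | b)
    if union == 0:
        warnings.warn("both masks are empty; Jaccard defined as 1",
                      UserWarning, stacklevel=2)
        return 1.0
    return float(np.count_nonzero(a & b) / union)


def confusion_counts(pred_mask: np.ndarray, true_mask: np.ndarray) -> ConfusionCounts:
    a, b = _as_bool(pred_mask), _as_bool(true_mask)
    if a.shape != b.shape:
        raise ValueError("masks are not aligned")
    return ConfusionCounts(
        tp=int(np.count_nonzero(a & b)),
        fp=int(np.count_nonzero(a & ~b)),
        fn=int(np.count_nonzero(~a & b)),
        tn=int(np.count_nonzero(~a & ~b)),
    )


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, sensitivity and specificity; undefined metrics are None."""
    out: dict[str, float | None] = {}
    out["accuracy"] = counts.tp + counts.tn
    out["accuracy"] = out["accuracy"] / counts.total if counts.total else None
    pos = counts.tp + counts.fn
    out["sensitivity"] = counts.tp / pos if pos else None
    neg = counts.tn + counts.fp
    out["specificity"] = counts.tn / neg if neg else None
    return out


def summarize_folds(values: np.ndarray) -> MetricSummary:
    """Mean and SEM (sample SD / sqrt(n)) across folds.

    With fewer than two folds the SEM is undefined and reported as None.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("need a 1-D, nonempty array of fold values")
    if v.size < 2:
        return MetricSummary(mean=float(v.mean()), sem=None, n_folds=int(v.size))
    sem = float(v.std(ddof=1) / np.sqrt(v.size))
    return MetricSummary(mean=float(v.mean()), sem=sem, n_folds=int(v.size))


def _overlay(rgb: np.ndarray, pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Prediction tinted cyan; ground-truth margin drawn as a white outline."""
    from scipy.ndimage import binary_dilation
    from skimage.morphology import disk

    img = rgb.copy()
    pred = _as_bool(pred)
    img[pred] = 0.5 * img[pred] + 0.5 * np.array([0.0, 1.0, 1.0])
    outline = binary_dilation(_as_bool(truth), structure=disk(1)) & ~_as_bool(truth)
    img[outline] = 1.0
    return np.clip(img, 0.0, 1.0)


def render_report(results: list[dict], out_dir: str | Path) -> pd.DataFrame:
    """Write per-sample overlays, a metrics CSV and a Jaccard-vs-k sweep plot.

    ``results`` rows carry at least ``method``, ``k``, ``fold`` and
    ``jaccard`` (plus ``accuracy`` / ``sensitivity`` / ``specificity`` when
    available); rows may attach ``sample_id``, ``rgb``, ``pred_mask`` and
    ``true_mask`` arrays for overlay rendering.  Returns the metrics table.
    """
    import matplotlib
    matplotlib.use("Agg")
    import imageio.v3 as iio
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metric_cols = ["method", "k", "fold", "jaccard", "accuracy",
                   "sensitivity", "specificity"]
    rows = []
    for res in results:
        rows.append({c: res.get(c) for c in metric_cols})
        if all(key in res for key in ("rgb", "pred_mask", "true_mask", "sample_id")):
            img = _overlay(res["rgb"], res["pred_mask"], res["true_mask"])
            iio.imwrite(
                out_dir / f"overlay_{res['method']}_{res['sample_id']}.png",
                (img * 255).astype(np.uint8),
            )
    table = pd.DataFrame(rows, columns=metric_cols)
    table.to_csv(out_dir / "metrics.csv", index=False)

    sweep = table.dropna(subset=["jaccard"])
    if not sweep.empty:
        fig, ax = plt.subplots(figsize=(6, 4))
        for method, grp in sweep.groupby("method"):
            curve = grp.groupby("k")["jaccard"].mean()
            ax.plot(curve.index, curve.values, marker="o", label=str(method))
        ax.set_xlabel("retained dimensions k")
        ax.set_ylabel("mean Jaccard coefficient")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out_dir / "jaccard_vs_k.png", dpi=120)
        plt.close(fig)
    return table
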