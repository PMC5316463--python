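"""Binarization and segmentation metrics for filtered vessel images.

A filtered image is thresholded into a vessel mask and compared against a
ground-truth mask through the confusion counts tp, tn, fp, fn:

    Se  = tp / (tp + fn)            sensitivity (vessel recall)
    Sp  = tn / (tn + fp)            specificity (background recall)
    Acc = (tp + tn) / N             overall pixel accuracy
    AUC = (Se + Sp) / 2             balanced accuracy (by definition here,
                                    not a ROC area)
    DC  = 2|A ∩ B| / (|A| + |B|)    Dice overlap = 2 tp / (2 tp + fp + fn)

Empty denominators (e.g. a truth mask with no vessel pixels) yield NaN and
the metric's name in ``MetricsReport.undefined`` — never a silent 0.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu

from .image import GrayImage

__all__ = ["ConfusionCounts", "MetricsReport", "binarize", "confusion",
           "report", "evaluate", "write_csv"]

CSV_FIELDS = ("file", "tp", "tn", "fp", "fn", "se", "sp", "acc", "auc", "dc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The five segmentation metrics plus their confusion counts.

    Undefined metrics are NaN and listed in ``undefined``.
    """

    se: float
    sp: float
    acc: float
    auc: float
    dc: float
    counts: ConfusionCounts
    undefined: frozenset = frozenset()


def binarize(image: GrayImage | np.ndarray, method: str = "otsu",
             threshold: float | None = None,
             polarity: str | None = None) -> np.ndarray:
    """Threshold an intensity image into a boolean vessel mask.

    For "dark" polarity the below-threshold class is vessel; for "bright"
    the above-threshold class.  ``method`` is "otsu" (default) or "fixed"
    (requires ``threshold``).  A constant image has no foreground: Otsu
    degenerates, a warning is emitted and the empty mask returned.

    The Otsu threshold is estimated on non-saturated pixels (more than
    one 8-bit quantization step away from 0 and 1) when any exist:
    salt-and-pepper impulses survive any bilateral-family filter nearly
    unchanged and the resulting endpoint classes can otherwise out-vote
    the vessel/background split in the between-class variance.  Every
    pixel is still classified against the resulting threshold.
    """
    if isinstance(image, GrayImage):
        vals = image.values
        polarity = polarity or image.polarity
    else:
        vals = np.asarray(image, dtype=np.float64)
        if polarity is None:
            raise ValueError("polarity is required for a plain array")
    if polarity not in ("dark", "bright"):
        raise ValueError(f"polarity must be 'dark' or 'bright', got {polarity!r}")

    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = float(threshold)
    elif method == "otsu":
        if np.ptp(vals) == 0.0:
            warnings.warn("constant image: Otsu threshold is degenerate, "
                          "returning an empty vessel mask", stacklevel=2)
            return np.zeros(vals.shape, dtype=bool)
        margin = 1.0 / 255.0
        interior = vals[(vals > margin) & (vals < 1.0 - margin)]
        if interior.size > 1 and np.ptp(interior) > 0.0:
            thr = float(threshold_otsu(interior))
        else:
            thr = float(threshold_otsu(vals))
    else:
        raise ValueError(f"unknown binarization method {method!r}")

    return vals < thr if polarity == "dark" else vals > thr


def confusion(pred: np.ndarray, truth: np.ndarray,
              fov: np.ndarray | None = None) -> ConfusionCounts:
    """Confusion counts of a predicted mask against ground truth.

    ``fov`` (optional boolean mask) restricts counting to field-of-view
    pixels, as needed for circular fundus frames.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs "
                         f"truth {truth.shape}")
    if fov is not None:
        fov = np.asarray(fov, dtype=bool)
        if fov.shape != pred.shape:
            raise ValueError("fov mask shape does not match the images")
        pred, truth = pred[fov], truth[fov]
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def _ratio(num: int, den: int, name: str, undefined: set) -> float:
    if den == 0:
        undefined.add(name)
        return float("nan")
    return num / den


def report(counts: ConfusionCounts) -> MetricsReport:
    """Derive the five metrics from confusion counts."""
    undefined: set = set()
    se = _ratio(counts.tp, counts.tp + counts.fn, "se", undefined)
    sp = _ratio(counts.tn, counts.tn + counts.fp, "sp", undefined)
    acc = _ratio(counts.tp + counts.tn, counts.total, "acc", undefined)
    dc = _ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn,
                "dc", undefined)
    auc = (se + sp) / 2.0
    if "se" in undefined or "sp" in undefined:
        undefined.add("auc")
    return MetricsReport(se=se, sp=sp, acc=acc, auc=auc, dc=dc,
                         counts=counts, undefined=frozenset(undefined))


def evaluate(pred: np.ndarray, truth: np.ndarray,
             fov: np.ndarray | None = None) -> MetricsReport:
    """Confusion + report in one step for a pair of masks."""
    return report(confusion(pred, truth, fov))


def write_csv(rows: dict[str, MetricsReport], path: str | Path) -> None:
    """Serialize reports as CSV, one row per image."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_FIELDS)
        for name, rep in rows.items():
            c = rep.counts
            writer.writerow([name, c.tp, c.tn, c.fp, c.fn,
                             *(f"{v:.6f}" for v in
                               (rep.se, rep.sp, rep.acc, rep.auc, rep.dc))])


def format_report(name: str, rep: MetricsReport) -> str:
    c = rep.counts
    return (f"{name}: tp={c.tp} tn={c.tn} fp={c.fp} fn={c.fn} | "
            f"Se={rep.se:.4f} Sp={rep.sp:.4f} Acc={rep.acc:.4f} "
            f"AUC={rep.auc:.4f} DC={rep.dc:.4f}")
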