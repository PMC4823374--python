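"""Segmentation quality metrics, structure counting and cross-validation.

Voxel metrics are one-vs-rest: a foreground label is fixed and every
other label counts as background.  TPR, FPR, ACC and JAC are the usual
confusion-count ratios; VOE = |FP - FN| / (TP + FN) measures the net
volume bias of the segmentation.

Structure counts treat each connected component (6-connectivity by
default, matching the CRF graph) as one object and discard components
below a size threshold; the count-error statistic averages the absolute
deviation from a reference count over a whole threshold range, so it
rewards segmentations whose counts are stable across thresholds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import ImageStack, LabelVolume

METRIC_NAMES = ("TPR", "FPR", "ACC", "JAC", "VOE")


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest voxel confusion counts."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_counts(pred: LabelVolume, gt: LabelVolume, foreground: int) -> ConfusionCounts:
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    p = pred.labels == foreground
    g = gt.labels == foreground
    return ConfusionCounts(
        TP=int(np.sum(p & g)),
        TN=int(np.sum(~p & ~g)),
        FP=int(np.sum(p & ~g)),
        FN=int(np.sum(~p & g)),
    )


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    """TPR/FPR/ACC/JAC/VOE from confusion counts; undefined ratios are NaN."""
    pos = c.TP + c.FN
    tpr = c.TP / pos if pos else math.nan
    voe = abs(c.FP - c.FN) / pos if pos else math.nan
    neg = c.FP + c.TN
    fpr = c.FP / neg if neg else math.nan
    union = c.TP + c.FP + c.FN
    jac = c.TP / union if union else math.nan
    acc = (c.TP + c.TN) / c.total if c.total else math.nan
    return {"TPR": tpr, "FPR": fpr, "ACC": acc, "JAC": jac, "VOE": voe}


def voxel_metrics(pred: LabelVolume, gt: LabelVolume, foreground: int) -> dict[str, float]:
    """One-vs-rest voxel metrics of a predicted labeling against ground truth."""
    return metrics_from_counts(confusion_counts(pred, gt, foreground))


# ---------------------------------------------------------------------------
# Connected-component counting
# ---------------------------------------------------------------------------

def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def component_sizes(labels: LabelVolume, target: int, connectivity: int = 6) -> np.ndarray:
    """Voxel counts of the connected components of one label, descending."""
    mask = labels.labels == target
    labeled, n = ndimage.label(mask, structure=_structure(connectivity))
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    sizes = np.bincount(labeled.ravel())[1:]
    return np.sort(sizes)[::-1].astype(np.int64)


def count_components(
    labels: LabelVolume, target: int, min_size: int = 0, connectivity: int = 6
) -> int:
    """Number of connected components of ``target`` with >= ``min_size`` voxels."""
    if min_size < 0:
        raise ValueError("min_size must be non-negative")
    sizes = component_sizes(labels, target, connectivity)
    return int(np.sum(sizes >= max(min_size, 1)))


@dataclass(frozen=True)
class CountSweep:
    """Component counts over a range of size thresholds plus the true count."""

    thresholds: tuple[int, ...]
    counts: tuple[int, ...]
    gt_count: int

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.counts):
            raise ValueError("thresholds and counts must have equal length")
        th = np.asarray(self.thresholds)
        if th.size and np.all(np.diff(th) >= 0):
            if np.any(np.diff(np.asarray(self.counts)) > 0):
                raise ValueError("counts must be non-increasing in the threshold")


def count_sweep(
    labels: LabelVolume,
    target: int,
    gt_count: int,
    thresholds: Iterable[int] | None = None,
    connectivity: int = 6,
) -> CountSweep:
    """Counts over the threshold range (default T = [10, 2000] integers)."""
    if thresholds is None:
        thresholds = range(10, 2001)
    thresholds = tuple(int(t) for t in thresholds)
    sizes = component_sizes(labels, target, connectivity)
    # sizes sorted descending: count at threshold t = # sizes >= t
    counts = tuple(int(np.searchsorted(-sizes, -t, side="right")) for t in thresholds)
    return CountSweep(thresholds=thresholds, counts=counts, gt_count=int(gt_count))


def count_error(sweep: CountSweep) -> float:
    """Mean absolute deviation of the counts from the reference count."""
    counts = np.asarray(sweep.counts, dtype=np.float64)
    return float(np.mean(np.abs(counts - sweep.gt_count)))


# ---------------------------------------------------------------------------
# Slice-block cross-validation over (sigma0, theta_xy)
# ---------------------------------------------------------------------------

def fold_blocks(n_slices: int, k: int) -> list[slice]:
    """k contiguous Z blocks; the remainder goes to the last block."""
    if k < 2 or k > n_slices:
        raise ValueError(f"k={k} incompatible with {n_slices} slices")
    block = n_slices // k
    out = []
    for i in range(k):
        start = i * block
        stop = (i + 1) * block if i < k - 1 else n_slices
        out.append(slice(start, stop))
    return out


def crossval_grid(
    stack: ImageStack,
    gt: LabelVolume,
    sigma0_list: Sequence[float],
    theta_list: Sequence[float],
    k: int = 5,
    n_scales: int = 4,
    extractor: str = "auto",
    connectivity: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Fold-wise metric table per (sigma0, theta_xy) parameter pair.

    For each fold, the classifier is trained on the ground-truth labels of
    the other k-1 contiguous slice blocks, the held-out block is
    classified and CRF-regularized, and one-vs-rest metrics are computed
    per non-background label.  Folds without labeled voxels are skipped
    with a warning.
    """
    from .classifier import predict_proba, train
    from .crf import CRFConfig, regularize_tiled
    from .features import ScaleSet, extract_features

    blocks = fold_blocks(stack.shape[2], k)
    rows = []
    fg_labels = [lab for lab in gt.ids() if lab != 1]
    for sigma0 in sigma0_list:
        feats = extract_features(stack, ScaleSet(sigma0=sigma0, n=n_scales), extractor)
        for fold, held in enumerate(blocks):
            train_labels = gt.labels.copy()
            train_labels[:, :, held] = 0
            if not (train_labels != 0).any():
                warnings.warn(f"fold {fold}: no labeled voxels, skipped", stacklevel=2)
                continue
            table = {0: "unlabeled", **{int(i): gt.label_table[int(i)] for i in gt.ids()}}
            model = train(feats, LabelVolume(train_labels, table), seed=seed)
            probs = predict_proba(model, feats)
            held_probs = type(probs)(
                probs=probs.probs[:, :, held],
                label_ids=probs.label_ids,
                label_table=probs.label_table,
            )
            gt_held = LabelVolume(gt.labels[:, :, held], gt.label_table)
            for theta in theta_list:
                config = CRFConfig(theta_xy=theta)
                pred = regularize_tiled(held_probs, config, rho=stack.rho)
                for lab in fg_labels:
                    m = voxel_metrics(pred, gt_held, lab)
                    rows.append(
                        {"sigma0": sigma0, "theta_xy": theta, "fold": fold, "label": lab, **m}
                    )
    return pd.DataFrame(rows, columns=["sigma0", "theta_xy", "fold", "label", *METRIC_NAMES])
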