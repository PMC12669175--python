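"""Segmentation evaluation: overlap metrics and the 95% Hausdorff distance.

All ratio metrics derive from the voxel-wise confusion counts; distances are
computed between boundary voxels (foreground voxels with at least one
face-adjacent background neighbor, the volume border counting as background)
in physical millimetres.  Degenerate denominators follow fixed conventions
so batch averaging is always defined:

* Dice/Jaccard/VS are 1 when both masks are empty, 0 when exactly one is;
* sensitivity/specificity are 1 when their reference class is absent;
* Kappa and MCC are 0 when a marginal is degenerate;
* HD95 is 0 when both masks are empty and NaN when exactly one is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "overlap_metrics",
    "hd95",
    "evaluate_pair",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = [
    "dice", "sen", "spe", "bacc", "acc", "ji", "kappa", "vs", "mcc", "hd95",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """The ten evaluation quantities; ``hd95`` in mm (NaN if undefined)."""

    dice: float
    sen: float
    spe: float
    bacc: float
    acc: float
    ji: float
    kappa: float
    vs: float
    mcc: float
    hd95: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_COLUMNS}


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Voxel-wise confusion counts for binary masks of identical shape."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def overlap_metrics(c: ConfusionCounts) -> MetricsReport:
    """All ratio metrics from confusion counts (distance field left NaN)."""
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    n = c.total
    dice = _ratio(2 * tp, 2 * tp + fp + fn, empty=1.0)
    ji = _ratio(tp, tp + fp + fn, empty=1.0)
    sen = _ratio(tp, tp + fn, empty=1.0)
    spe = _ratio(tn, tn + fp, empty=1.0)
    acc = _ratio(tp + tn, n, empty=1.0)
    bacc = 0.5 * (sen + spe)
    vs = 1.0 - _ratio(abs(fp - fn), 2 * tp + fp + fn, empty=0.0)
    # chance-corrected agreement
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = 0.0 if pe == 1.0 else (po - pe) / (1.0 - pe)
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = 0.0 if mcc_den == 0.0 else (tp * tn - fp * fn) / mcc_den
    return MetricsReport(dice, sen, spe, bacc, acc, ji, kappa, vs, mcc)


def _ratio(num: float, den: float, empty: float) -> float:
    return float(num) / float(den) if den else empty


# ---------------------------------------------------------------------------
# Surface distance


def _boundary_points(mask: np.ndarray, spacing) -> np.ndarray:
    """Physical coordinates of boundary voxels (face connectivity,
    volume border treated as background)."""
    struct = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    boundary = mask & ~interior
    idx = np.argwhere(boundary)
    return idx * np.asarray(spacing, dtype=float)


def hd95(pred: np.ndarray, truth: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """95th-percentile symmetric surface distance in millimetres.

    Directed distances from every boundary voxel of one mask to the nearest
    boundary voxel of the other; the 95th percentile (linear interpolation)
    is taken per direction and the maximum of the two directions returned.
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    p_empty, t_empty = not pred.any(), not truth.any()
    if p_empty and t_empty:
        return 0.0
    if p_empty or t_empty:
        return math.nan
    a = _boundary_points(pred, spacing)
    b = _boundary_points(truth, spacing)
    d_ab = cKDTree(b).query(a, k=1)[0]
    d_ba = cKDTree(a).query(b, k=1)[0]
    return float(
        max(np.percentile(d_ab, 95), np.percentile(d_ba, 95))
    )


def evaluate_pair(
    pred: np.ndarray, truth: np.ndarray, spacing=(1.0, 1.0, 1.0)
) -> MetricsReport:
    """Full ten-metric report for one prediction/ground-truth pair."""
    report = overlap_metrics(confusion(pred, truth))
    report.hd95 = hd95(pred, truth, spacing)
    return report
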