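"""Training losses and segmentation evaluation metrics.

The F-loss is an F-beta-style overlap loss,

    L_F(y, y_hat) = 1 - (1 + b^2) * sum(y_hat * y)
                        / (sum(y_hat) + b^2 * sum(y) + eps),

which reduces to the Dice loss at beta = 1 and weights recall more heavily
for beta > 1 (beta = 2 is the working default: missing tumour voxels is
costlier than over-contouring at the coarse stage). The two-stage training
objective is the convex combination alpha * L_KsPC + (1 - alpha) * L_CNN
with alpha = 0.7.

Evaluation uses the confusion-matrix metrics (Dice, precision, recall) and
the robustified Hausdorff distance HD95: the 95th percentile of the pooled
directed boundary-to-boundary nearest-neighbour distances, in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

from .grid import SegmentationMask


def f_loss(y, y_hat, beta: float = 2.0, eps: float = 1e-8) -> float:
    """F-beta overlap loss between a binary target and a (soft) prediction."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    if not (np.isfinite(beta) and beta > 0):
        raise ValueError("beta must be a positive finite real")
    b2 = beta * beta
    num = (1.0 + b2) * float((y_hat * y).sum())
    den = float(y_hat.sum()) + b2 * float(y.sum()) + eps
    return 1.0 - num / den


def final_loss(loss_kspc: float, loss_cnn: float, alpha: float = 0.7) -> float:
    """Weighted two-stage loss alpha * L_KsPC + (1 - alpha) * L_CNN."""
    if not (np.isfinite(loss_kspc) and np.isfinite(loss_cnn)):
        raise ValueError("losses must be finite")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return alpha * loss_kspc + (1.0 - alpha) * loss_cnn


@dataclass
class EvalReport:
    """Overlap and distance metrics between a predicted and a reference mask."""

    dice: float
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int
    hd95: float | None = None  # mm; None when undefined (an empty mask)

    def as_record(self) -> str:
        hd = "nan" if self.hd95 is None else f"{self.hd95:.4f}"
        return (
            f"dice={self.dice:.4f}\thd95_mm={hd}\tprecision={self.precision:.4f}"
            f"\trecall={self.recall:.4f}\ttp={self.tp}\tfp={self.fp}\tfn={self.fn}"
        )


def confusion_metrics(truth: SegmentationMask, pred: SegmentationMask) -> EvalReport:
    """Dice, precision and recall from the voxel-wise confusion matrix.

    Empty-denominator conventions: both masks empty -> all metrics 1;
    truth empty but prediction non-empty -> recall 1, precision and dice 0.
    """
    if not truth.same_geometry(pred):
        raise ValueError("truth and prediction geometries do not match")
    t = truth.indicator
    p = pred.indicator
    tp = int((t & p).sum())
    fp = int((~t & p).sum())
    fn = int((t & ~p).sum())
    dice = 2.0 * tp / (2.0 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 1.0
    precision = tp / (tp + fp) if (tp + fp) > 0 else 1.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 1.0
    return EvalReport(dice=dice, precision=precision, recall=recall, tp=tp, fp=fp, fn=fn)


class UndefinedDistanceError(ValueError):
    """Raised when a boundary distance is requested for an empty mask."""


def _boundary_points_mm(mask: SegmentationMask) -> np.ndarray:
    """mm coordinates of the 6-connectivity surface voxels of a mask."""
    structure = np.zeros((3, 3, 3), dtype=bool)
    structure[1, 1, :] = structure[1, :, 1] = structure[:, 1, 1] = True
    interior = binary_erosion(mask.indicator, structure=structure, border_value=0)
    boundary = mask.indicator & ~interior
    idx = np.argwhere(boundary)
    return idx * np.asarray(mask.spacing)[None, :] + np.asarray(mask.origin)[None, :]


def hd95(a: SegmentationMask, b: SegmentationMask) -> float:
    """95th-percentile Hausdorff distance between two masks, in mm.

    Pools the two directed nearest-neighbour distance lists between the
    boundary voxel sets and takes the lower nearest-rank 95th percentile.
    Symmetric in its arguments; 0 for identical masks.
    """
    if not a.same_geometry(b):
        raise ValueError("mask geometries do not match")
    if a.is_empty() or b.is_empty():
        raise UndefinedDistanceError("HD95 is undefined for an empty mask")
    pa = _boundary_points_mm(a)
    pb = _boundary_points_mm(b)
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    pooled = np.sort(np.concatenate([d_ab, d_ba]))
    rank = int(np.ceil(0.95 * pooled.size)) - 1
    return float(pooled[max(rank, 0)])


def evaluate(truth: SegmentationMask, pred: SegmentationMask) -> EvalReport:
    """Full evaluation report; HD95 is None when either mask is empty."""
    report = confusion_metrics(truth, pred)
    if not (truth.is_empty() or pred.is_empty()):
        report.hd95 = hd95(truth, pred)
    return report
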