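"""BraTS-style evaluation: Dice, sensitivity, PPV and HD95 per region.

Overlap statistics are exact voxel counts; HD95 is the maximum of the two
directed 95th-percentile surface distances, computed between surface-voxel
centers scaled by the physical spacing, in millimeters.

Degenerate-region conventions (the common BraTS tooling behavior): if both
prediction and truth are empty the case is perfect (dice/sensitivity/ppv 1,
hd95 0); if exactly one is empty the overlap scores are 0 and hd95 is a
worst-case sentinel, the physical diagonal of the volume.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import InvalidShapeError
from .io_brats import LabelVolume, RegionMasks, labels_to_regions

__all__ = ["ConfusionCounts", "RegionMetrics", "MetricReport", "confusion",
           "overlap_metrics", "hd95", "evaluate_masks", "evaluate_labels"]


@dataclass
class ConfusionCounts:
    n_tp: int
    n_fp: int
    n_fn: int


@dataclass
class RegionMetrics:
    """Scores for one evaluation region; hd95 is in millimeters."""

    dice: float
    sensitivity: float
    ppv: float
    hd95: float

    def as_dict(self) -> dict[str, float]:
        return {"dice": self.dice, "sensitivity": self.sensitivity,
                "ppv": self.ppv, "hd95": self.hd95}


@dataclass
class MetricReport:
    """Per-region metrics for one case (regions wt, tc, et)."""

    wt: RegionMetrics
    tc: RegionMetrics
    et: RegionMetrics

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {"wt": self.wt.as_dict(), "tc": self.tc.as_dict(),
                "et": self.et.as_dict()}

    def flat(self) -> dict[str, float]:
        return {f"{r}_{k}": v for r, d in self.as_dict().items()
                for k, v in d.items()}


def confusion(pred_mask: np.ndarray, true_mask: np.ndarray) -> ConfusionCounts:
    """Exact TP/FP/FN voxel counts for two binary masks."""
    pred = np.asarray(pred_mask, dtype=bool)
    true = np.asarray(true_mask, dtype=bool)
    if pred.shape != true.shape:
        raise InvalidShapeError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    tp = int(np.count_nonzero(pred & true))
    fp = int(np.count_nonzero(pred & ~true))
    fn = int(np.count_nonzero(~pred & true))
    return ConfusionCounts(tp, fp, fn)


def overlap_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(dice, sensitivity, ppv) from voxel counts, with empty conventions."""
    tp, fp, fn = c.n_tp, c.n_fp, c.n_fn
    if tp == 0 and fp == 0 and fn == 0:      # both masks empty
        return 1.0, 1.0, 1.0
    dice = 2.0 * tp / (fp + 2.0 * tp + fn)
    sens = tp / (tp + fn) if tp + fn else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    return dice, sens, ppv


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates of foreground voxels with a 6-connected background
    neighbor; the volume border counts as background."""
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return np.argwhere(mask & ~eroded)


def _volume_diagonal_mm(shape, spacing) -> float:
    return float(np.linalg.norm([s * sp for s, sp in zip(shape, spacing)]))


def hd95(pred_mask: np.ndarray, true_mask: np.ndarray,
         spacing=(1.0, 1.0, 1.0)) -> float:
    """95th-percentile symmetric Hausdorff surface distance in millimeters.

    For each surface voxel of one mask the minimum spacing-scaled distance
    to the other mask's surface is taken; the score is the maximum of the
    two directed 95th percentiles (linear-interpolation quantile).
    Empty-mask conventions: both empty -> 0; one empty -> volume diagonal.
    """
    pred = np.asarray(pred_mask, dtype=bool)
    true = np.asarray(true_mask, dtype=bool)
    if pred.shape != true.shape:
        raise InvalidShapeError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    p_empty, t_empty = not pred.any(), not true.any()
    if p_empty and t_empty:
        return 0.0
    if p_empty or t_empty:
        return _volume_diagonal_mm(pred.shape, spacing)
    sp = np.asarray(spacing, dtype=float)
    surf_p = _surface_voxels(pred) * sp
    surf_t = _surface_voxels(true) * sp
    d_p_to_t = cKDTree(surf_t).query(surf_p)[0]
    d_t_to_p = cKDTree(surf_p).query(surf_t)[0]
    return float(max(np.percentile(d_p_to_t, 95), np.percentile(d_t_to_p, 95)))


def _region_metrics(pred: np.ndarray, true: np.ndarray, spacing) -> RegionMetrics:
    dice, sens, ppv = overlap_metrics(confusion(pred, true))
    return RegionMetrics(dice=dice, sensitivity=sens, ppv=ppv,
                         hd95=hd95(pred, true, spacing))


def evaluate_masks(pred: RegionMasks, true: RegionMasks, spacing) -> MetricReport:
    return MetricReport(
        wt=_region_metrics(pred.wt, true.wt, spacing),
        tc=_region_metrics(pred.tc, true.tc, spacing),
        et=_region_metrics(pred.et, true.et, spacing),
    )


def evaluate_labels(pred: LabelVolume, true: LabelVolume) -> MetricReport:
    """Full per-case report on the nested WT/TC/ET regions."""
    if pred.shape != true.shape:
        raise InvalidShapeError(
            f"prediction shape {pred.shape} != truth shape {true.shape}")
    return evaluate_masks(labels_to_regions(pred), labels_to_regions(true),
                          true.spacing)
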