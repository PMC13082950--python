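"""Segmentation evaluation metrics.

Binary (OCTA-style) task: Dice (DSC), precision (PRE), hard-skeleton
centerline Dice (clDice) and average symmetric surface distance (ASD, mm).
Multi-class (CoW-style) task: per-class Dice and its unweighted macro mean.

Conventions (documented, config-switchable where noted):
  * DSC / clDice with both masks empty -> 1 (correctly predicting absence);
  * precision with no predicted positives -> 1 if the reference is also
    empty, else 0;
  * ASD is undefined when either surface is empty and raises;
  * macro Dice scores a class absent from both prediction and reference as 1
    by default (``absent_policy='score_one'``) or drops it from the mean
    (``absent_policy='exclude'``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

__all__ = ["MetricReport", "dsc", "precision", "cl_dice_metric", "asd",
           "macro_dice", "binary_report"]


@dataclass
class MetricReport:
    task: str
    values: dict = field(default_factory=dict)
    per_class_dice: np.ndarray | None = None

    def __getitem__(self, key):
        return self.values[key]

    def as_dict(self):
        d = {k: (None if v is None else float(v)) for k, v in self.values.items()}
        if self.per_class_dice is not None:
            d["per_class_dice"] = [float(x) for x in self.per_class_dice]
        d["task"] = self.task
        return d


def _check_binary(pred, gt):
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    return pred, gt


def dsc(pred, gt) -> float:
    """Dice similarity 2|P∩G| / (|P|+|G|); 1 when both are empty."""
    pred, gt = _check_binary(pred, gt)
    denom = pred.sum() + gt.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, gt).sum() / denom)


def precision(pred, gt) -> float:
    """TP / (TP + FP); empty prediction scores 1 iff the reference is empty too."""
    pred, gt = _check_binary(pred, gt)
    tp = np.logical_and(pred, gt).sum()
    pp = pred.sum()
    if pp == 0:
        return 1.0 if gt.sum() == 0 else 0.0
    return float(tp / pp)


def _skeleton(mask):
    return skeletonize(mask.astype(np.uint8)).astype(bool)


def cl_dice_metric(pred, gt) -> float:
    """Centerline Dice on hard morphological skeletons.

    Tprec = |skel(P) ∩ G| / |skel(P)|, Tsens = |skel(G) ∩ P| / |skel(G)|;
    harmonically combined. Sensitive to breaks that barely move plain Dice.
    """
    pred, gt = _check_binary(pred, gt)
    if not pred.any() and not gt.any():
        return 1.0
    sp, sg = _skeleton(pred), _skeleton(gt)
    if sp.sum() == 0 or sg.sum() == 0:
        return 0.0
    tprec = np.logical_and(sp, gt).sum() / sp.sum()
    tsens = np.logical_and(sg, pred).sum() / sg.sum()
    if tprec + tsens == 0:
        return 0.0
    return float(2.0 * tprec * tsens / (tprec + tsens))


def _surface(mask):
    """Foreground voxels with at least one background 6-neighbor (array
    boundaries count as background)."""
    padded = np.pad(mask, 1)
    er = ndimage.binary_erosion(
        padded, structure=ndimage.generate_binary_structure(3, 1))
    return mask & ~er[1:-1, 1:-1, 1:-1]


def asd(pred, gt, spacing=(1.0, 1.0, 1.0)) -> float:
    """Average symmetric surface distance in mm.

    Mean nearest-surface distance from P's surface to G's and vice versa,
    averaged over the two directions.
    """
    pred, gt = _check_binary(pred, gt)
    if not pred.any() or not gt.any():
        raise ValueError("ASD is undefined for an empty mask")
    sp, sg = _surface(pred), _surface(gt)
    d_to_g = ndimage.distance_transform_edt(~sg, sampling=spacing)
    d_to_p = ndimage.distance_transform_edt(~sp, sampling=spacing)
    return float(0.5 * (d_to_g[sp].mean() + d_to_p[sg].mean()))


def macro_dice(pred_labels, gt_labels, n_classes: int = 14,
               absent_policy: str = "score_one") -> MetricReport:
    """Per-class Dice (2TP / (2TP + FP + FN)) and the unweighted macro mean
    over the ``n_classes - 1`` foreground classes."""
    pred_labels = np.asarray(pred_labels)
    gt_labels = np.asarray(gt_labels)
    if pred_labels.shape != gt_labels.shape:
        raise ValueError("shape mismatch")
    for arr, name in ((pred_labels, "pred"), (gt_labels, "gt")):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} labels outside [0, {n_classes - 1}]")
    per = np.zeros(n_classes - 1, dtype=float)
    absent = np.zeros(n_classes - 1, dtype=bool)
    for c in range(1, n_classes):
        p, g = pred_labels == c, gt_labels == c
        tp = np.logical_and(p, g).sum()
        fp = p.sum() - tp
        fn = g.sum() - tp
        if tp + fp + fn == 0:
            per[c - 1], absent[c - 1] = 1.0, True
        else:
            per[c - 1] = 2.0 * tp / (2.0 * tp + fp + fn)
    if absent_policy == "score_one":
        mean = float(per.mean())
    elif absent_policy == "exclude":
        kept = per[~absent]
        mean = float(kept.mean()) if kept.size else 1.0
    else:
        raise ValueError(f"unknown absent_policy {absent_policy!r}")
    return MetricReport("cow", {"mean_dice": mean}, per_class_dice=per)


def binary_report(pred, gt, spacing=(1.0, 1.0, 1.0)) -> MetricReport:
    """DSC / PRE / clDice / ASD bundle for the binary vessel task."""
    values = {
        "dsc": dsc(pred, gt),
        "pre": precision(pred, gt),
        "cldice": cl_dice_metric(pred, gt),
    }
    try:
        values["asd_mm"] = asd(pred, gt, spacing)
    except ValueError:
        values["asd_mm"] = None  # undefined (empty mask), reported as missing
    return MetricReport("octa", values)
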