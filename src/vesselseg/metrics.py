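"""Segmentation quality metrics: voxel overlap, centerline Dice, Hausdorff.

Overlap metrics (precision, recall, Dice, Jaccard) compare prediction and
truth voxel-by-voxel.  clDice measures topology preservation instead: the
fraction of the prediction's centerline lying inside the truth (topology
precision) and of the truth's centerline inside the prediction (topology
sensitivity), combined harmonically — a prediction can have near-perfect
Dice yet poor clDice if it breaks thin vessels.  The Hausdorff distance is
the symmetrized maximum Euclidean distance between the two masks' surface
voxels, computed via distance transforms.

Conventions: two empty masks agree perfectly (all overlap metrics 1.0, and
clDice 1.0 for two empty skeletons); an empty mask against a non-empty one
scores 0.0.  Hausdorff is undefined for empty masks and raises.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["ConfusionCounts", "confusion_counts", "overlap_metrics", "cl_dice", "hausdorff"]

from dataclasses import dataclass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _check_pair(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred) > 0
    t = np.asarray(truth) > 0
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    return p, t


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    p, t = _check_pair(pred, truth)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def overlap_metrics(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """precision, recall, dice, jaccard from the voxel confusion counts."""
    c = confusion_counts(pred, truth)
    if c.tp + c.fp + c.fn == 0:  # both empty
        return {"precision": 1.0, "recall": 1.0, "dice": 1.0, "jaccard": 1.0}

    def ratio(num: float, den: float) -> float:
        return num / den if den else 0.0

    return {
        "precision": ratio(c.tp, c.tp + c.fp),
        "recall": ratio(c.tp, c.tp + c.fn),
        "dice": ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        "jaccard": ratio(c.tp, c.tp + c.fp + c.fn),
    }


def cl_dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Centerline Dice: harmonic mean of skeleton-in-mask precision and sensitivity.

    Skeletons come from the same 3D thinning used for morphometry, so a
    topology break in either mask is penalized much harder than a uniform
    one-voxel boundary error.
    """
    from vesselseg.vasc_analysis import skeleton_mask

    p, t = _check_pair(pred, truth)
    sp = skeleton_mask(p)
    st = skeleton_mask(t)
    n_sp, n_st = int(sp.sum()), int(st.sum())
    if n_sp == 0 and n_st == 0:
        return 1.0
    if n_sp == 0 or n_st == 0:
        return 0.0
    tprec = float(np.count_nonzero(sp & t)) / n_sp
    tsens = float(np.count_nonzero(st & p)) / n_st
    if tprec + tsens == 0:
        return 0.0
    return 2 * tprec * tsens / (tprec + tsens)


def _surface(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, ndimage.generate_binary_structure(3, 1), border_value=0)
    return mask & ~eroded


def hausdorff(
    pred: np.ndarray,
    truth: np.ndarray,
    percentile: float | None = None,
    voxel_size: tuple[float, float, float] | None = None,
) -> float:
    """Symmetric surface Hausdorff distance in voxel units (or physical units).

    ``percentile`` switches to the robust variant (e.g. 95 for HD95).
    Raises on an empty mask, where the metric is undefined.
    """
    p, t = _check_pair(pred, truth)
    if not p.any() or not t.any():
        raise ValueError("hausdorff is undefined for an empty mask")
    sp, st = _surface(p), _surface(t)
    sampling = voxel_size if voxel_size is not None else (1.0, 1.0, 1.0)
    # distance from every voxel to the nearest surface voxel of the other mask
    d_to_t = ndimage.distance_transform_edt(~st, sampling=sampling)
    d_to_p = ndimage.distance_transform_edt(~sp, sampling=sampling)
    fwd = d_to_t[sp]
    bwd = d_to_p[st]
    if percentile is None:
        return float(max(fwd.max(), bwd.max()))
    return float(max(np.percentile(fwd, percentile), np.percentile(bwd, percentile)))
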