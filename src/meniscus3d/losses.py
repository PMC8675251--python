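"""Training losses: class-weighted BCE, L1 box loss, 3D Generalized IoU.

The total training objective of the multi-task detector is the unweighted
sum

    L = L_BCE + L_L1 + L_GIoU

where L_BCE is a binary cross-entropy over the six sub-region tear labels
with per-class inverse-frequency weights, L_L1 is the mean (over the batch)
of the summed absolute differences of the 12 box values, and L_GIoU is the
Generalized IoU loss

    L_GIoU = 1 - IoU + |C \\ (B u B_hat)| / |C|

with C the axis-aligned envelope (convex hull) of both boxes.  The GIoU term
is computed per meniscus and averaged over structure and batch.

All loss functions accept either autodiff Tensors (training path) or plain
arrays and return a scalar Tensor.  A voxelized GIoU computed by counting on
a rasterised lattice is provided as an independent oracle for testing the
analytic geometry.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "class_weights", "weighted_bce", "l1_box_loss", "giou_loss",
    "total_loss", "voxelized_giou_oracle", "GIOU_SIZE_EPS",
]

#: zero-size boxes (single-voxel structures under the literal size formula)
#: are clamped to this relative extent before GIoU to avoid 0/0
GIOU_SIZE_EPS = 1e-6


def class_weights(labels: np.ndarray) -> np.ndarray:
    """Balanced inverse-prevalence weights w_c = N / (2 * N_pos,c).

    Requires at least one positive and one negative per class in the
    training labels.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2 or labels.shape[1] != 6:
        raise ValueError("labels must be an N x 6 binary matrix")
    n = labels.shape[0]
    n_pos = labels.sum(axis=0).astype(np.float64)
    if np.any(n_pos == 0) or np.any(n_pos == n):
        raise ValueError("each class needs at least one positive and one negative")
    return (n / (2.0 * n_pos)).astype(np.float32)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def weighted_bce(logits, targets, w) -> Tensor:
    """Class-weighted binary cross-entropy over an N x 6 batch.

    Mean over the batch, sum over classes, each class bracket multiplied by
    its weight; computed from logits with the stabilised log-sigmoid so large
    scores do not overflow.  Always nonnegative.
    """
    logits = _as_tensor(logits)
    targets = np.asarray(targets, dtype=np.float32)
    if not np.isin(targets, (0.0, 1.0)).all():
        raise ValueError("targets must be binary")
    if logits.shape != targets.shape:
        raise ValueError("logits and targets shapes differ")
    w = np.broadcast_to(np.asarray(w, dtype=np.float32), (targets.shape[1],))
    n = targets.shape[0]
    pos = logits.logsigmoid() * Tensor(targets)
    neg = (-logits).logsigmoid() * Tensor(1.0 - targets)
    per_elem = (pos + neg) * Tensor(w[None, :])
    return -(per_elem.sum() / n)


def l1_box_loss(predicted, target) -> Tensor:
    """Mean over the batch of the summed |differences| of all 12 box values."""
    predicted = _as_tensor(predicted)
    target = _as_tensor(target)
    if predicted.shape != target.shape:
        raise ValueError("predicted and target batches must have equal shape")
    n = predicted.shape[0] if predicted.ndim > 1 else 1
    return (predicted - target).abs().sum() / n


def _boxes_to_corners(boxes: Tensor):
    """(..., 6) center+size -> (lo, hi) tensors of shape (..., 3)."""
    center = boxes[..., :3]
    size = boxes[..., 3:].maximum(GIOU_SIZE_EPS)
    half = size * 0.5
    return center - half, center + half, size


def _giou_values(pred: Tensor, tgt: Tensor) -> Tensor:
    """Elementwise GIoU loss for (..., 6) box tensors -> (...) tensor."""
    plo, phi, psize = _boxes_to_corners(pred)
    tlo, thi, tsize = _boxes_to_corners(tgt)
    overlap = phi.minimum(thi) - plo.maximum(tlo)
    overlap = overlap.maximum(0.0)
    inter = overlap[..., 0] * overlap[..., 1] * overlap[..., 2]
    vol_p = psize[..., 0] * psize[..., 1] * psize[..., 2]
    vol_t = tsize[..., 0] * tsize[..., 1] * tsize[..., 2]
    union = vol_p + vol_t - inter
    hull_ext = phi.maximum(thi) - plo.minimum(tlo)
    hull = hull_ext[..., 0] * hull_ext[..., 1] * hull_ext[..., 2]
    iou = inter / union
    return 1.0 - iou + (hull - union) / hull


def giou_loss(predicted, target) -> Tensor:
    """Generalized IoU loss between center+size boxes.

    Accepts a single box (6 values), a batch (N, 6) or a per-structure batch
    (N, 2, 6); in batch form the per-structure values are averaged over
    structures then over the batch.  Both boxes having zero volume is
    rejected (the IoU would be 0/0) unless the epsilon clamp resolves it.
    """
    predicted = _as_tensor(predicted)
    target = _as_tensor(target)
    if predicted.shape != target.shape or predicted.shape[-1] != 6:
        raise ValueError("boxes must be (..., 6) arrays of matching shape")
    if np.any(np.asarray(predicted.data[..., 3:]) < 0) or np.any(target.data[..., 3:] < 0):
        raise ValueError("box sizes must be nonnegative")
    return _giou_values(predicted, target).mean()


def total_loss(logits, targets, predicted_boxes, target_boxes, w):
    """L = L_BCE + L_L1 + L_GIoU; returns (total, components dict)."""
    bce = weighted_bce(logits, targets, w)
    l1 = l1_box_loss(predicted_boxes, target_boxes)
    pred = _as_tensor(predicted_boxes)
    tgt = _as_tensor(target_boxes)
    if pred.shape[-1] == 12:
        pred = pred.reshape(pred.shape[:-1] + (2, 6))
        tgt = tgt.reshape(tgt.shape[:-1] + (2, 6))
    giou = giou_loss(pred, tgt)
    total = bce + l1 + giou
    return total, {"bce": bce.item(), "l1": l1.item(), "giou": giou.item(),
                   "total": total.item()}


def voxelized_giou_oracle(predicted, target, resolution: int = 100) -> float:
    """GIoU loss by voxel counting on a resolution^3 lattice (test oracle).

    Boxes are rasterised by testing voxel centers against the corner-form
    bounds; IoU and the hull term are ratios of voxel counts.
    """
    if resolution < 10:
        raise ValueError("resolution must be >= 10")

    def corners(box):
        box = np.asarray(box.to_array() if hasattr(box, "to_array") else box,
                         dtype=np.float64).reshape(6)
        c, s = box[:3], np.maximum(box[3:], GIOU_SIZE_EPS)
        return c - s / 2.0, c + s / 2.0

    plo, phi = corners(predicted)
    tlo, thi = corners(target)
    lo = np.minimum(plo, tlo).min()
    hi = np.maximum(phi, thi).max()
    centers = lo + (np.arange(resolution) + 0.5) * (hi - lo) / resolution

    def rasterize(blo, bhi):
        axes = [(centers >= blo[a]) & (centers <= bhi[a]) for a in range(3)]
        return axes[0][:, None, None] & axes[1][None, :, None] & axes[2][None, None, :]

    in_p = rasterize(plo, phi)
    in_t = rasterize(tlo, thi)
    inter = np.count_nonzero(in_p & in_t)
    union = np.count_nonzero(in_p | in_t)
    hlo = np.minimum(plo, tlo)
    hhi = np.maximum(phi, thi)
    hull = np.count_nonzero(rasterize(hlo, hhi))
    if union == 0 or hull == 0:
        raise ValueError("degenerate rasterisation: increase resolution")
    iou = inter / union
    return float(1.0 - iou + (hull - union) / hull)
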