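"""On-the-fly training augmentation.

Each augmentation (crop, horizontal flip, in-plane rotation, Gaussian noise,
intensity scaling) is applied independently with probability
``apply_prob`` (default 0.5).  Geometric transforms are applied identically
to the image and the label mask, and the ground-truth boxes are afterwards
recomputed from the transformed mask so regression targets stay truthful.

A "horizontal flip" of a sagittal volume mirrors the in-plane
anterior-posterior (column) axis; the anterior-horn and posterior-horn
labels of both menisci are swapped accordingly.

Cropping differs per approach: the full-volume approaches crop away up to a
per-axis fraction of the grid while keeping the meniscal region inside the
window; the RoI-cropped approach instead samples the crop window uniformly
between the tight box union and a 20%-margined envelope.  The caller
resamples the result to the approach's fixed input shape.

Noise is voxel-wise Gaussian with mean 0.1 and standard deviation 0.5 (on
standardised intensities); the intensity factor is uniform on [0.9, 1.1];
rotation angles are uniform on +-5 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import box_from_mask, _margined_voxel_bounds

__all__ = ["AugmentationSpec", "augment", "flip_label_order"]

#: label permutation under an anterior-posterior mirror
FLIP_LABEL_ORDER = (2, 1, 0, 5, 4, 3)


def flip_label_order(labels: np.ndarray) -> np.ndarray:
    return np.asarray(labels)[list(FLIP_LABEL_ORDER)]


@dataclass(frozen=True)
class AugmentationSpec:
    crop_fractions: tuple = (0.2, 0.2, 0.1)   # (slice, row, col) max crop
    flip_prob: float = 0.5
    rotation_range: float = 5.0               # degrees, uniform +-range
    noise_mean: float = 0.1
    noise_sd: float = 0.5
    intensity_range: tuple = (0.9, 1.1)
    apply_prob: float = 0.5
    roi_margin: float = 0.2                   # bb_crop: max crop margin

    def __post_init__(self):
        for p in (self.flip_prob, self.apply_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.rotation_range < 0:
            raise ValueError("rotation range must be symmetric (nonnegative)")


def _mask_bbox(mask: np.ndarray) -> tuple:
    coords = np.nonzero(mask > 0)
    lo = np.array([c.min() for c in coords])
    hi = np.array([c.max() for c in coords])
    return lo, hi


def _crop_keeping_roi(image, mask, fractions, rng):
    """Crop up to fraction f per axis, keeping all structure voxels inside."""
    lo, hi = _mask_bbox(mask)
    shape = np.asarray(mask.shape)
    slices = []
    for ax in range(3):
        max_crop = int(np.floor(rng.uniform(0.0, fractions[ax]) * shape[ax]))
        width = shape[ax] - max_crop
        width = max(width, hi[ax] - lo[ax] + 1)  # never cut the RoI
        off_lo = max(0, hi[ax] + 1 - width)
        off_hi = min(lo[ax], shape[ax] - width)
        offset = int(rng.integers(off_lo, off_hi + 1)) if off_hi >= off_lo else off_lo
        slices.append(slice(offset, offset + width))
    sl = tuple(slices)
    return image[sl], mask[sl]


def _crop_roi_jitter(image, mask, max_margin, rng):
    """Crop between the tight meniscal box union and a margined envelope."""
    boxes = [box_from_mask(mask, s) for s in (1, 2)]
    tight_lo, tight_hi = _margined_voxel_bounds(boxes, mask.shape, 0.0)
    wide_lo, wide_hi = _margined_voxel_bounds(boxes, mask.shape, max_margin)
    lo = np.array([int(rng.integers(wide_lo[a], tight_lo[a] + 1)) for a in range(3)])
    hi = np.array([int(rng.integers(tight_hi[a], wide_hi[a] + 1)) for a in range(3)])
    sl = tuple(slice(lo[a], hi[a]) for a in range(3))
    return image[sl], mask[sl]


def _rotate_inplane(image, mask, angle):
    """Rotate in the (row, col) plane about the slice axis."""
    img = ndimage.rotate(image, angle, axes=(1, 2), reshape=False,
                         order=1, mode="nearest")
    msk = ndimage.rotate(mask, angle, axes=(1, 2), reshape=False,
                         order=0, mode="constant", cval=0)
    return img, msk


def augment(image: np.ndarray, mask: np.ndarray, labels: np.ndarray,
            spec: AugmentationSpec, approach: str,
            rng: np.random.Generator):
    """Apply the augmentation pipeline to one sample.

    Returns ``(image, mask, labels)``; the caller recomputes boxes from the
    returned mask and resamples to the model's input shape.
    """
    image = np.asarray(image, dtype=np.float32)
    mask = np.asarray(mask)
    labels = np.asarray(labels).copy()

    if rng.random() < spec.flip_prob:
        image = image[:, :, ::-1].copy()
        mask = mask[:, :, ::-1].copy()
        labels = flip_label_order(labels)

    if spec.rotation_range > 0 and rng.random() < spec.apply_prob:
        angle = float(rng.uniform(-spec.rotation_range, spec.rotation_range))
        image, mask = _rotate_inplane(image, mask, angle)
        if not (mask == 1).any() or not (mask == 2).any():
            raise ValueError("rotation removed a structure from the grid")

    if rng.random() < spec.apply_prob:
        if approach == "bb_crop":
            image, mask = _crop_roi_jitter(image, mask, spec.roi_margin, rng)
        else:
            image, mask = _crop_keeping_roi(image, mask, spec.crop_fractions, rng)

    if rng.random() < spec.apply_prob:
        factor = float(rng.uniform(*spec.intensity_range))
        image = image * factor

    if spec.noise_sd > 0 and rng.random() < spec.apply_prob:
        image = image + rng.normal(spec.noise_mean, spec.noise_sd,
                                   size=image.shape).astype(np.float32)

    return image.astype(np.float32), mask, labels
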