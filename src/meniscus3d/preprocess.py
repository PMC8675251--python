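"""Intensity normalisation, bounding-box derivation and RoI cropping.

Axis and coordinate conventions (used package-wide):

* Volumes are numpy arrays indexed ``(slice, row, col)`` — sagittal slices
  along axis 0 (medial to lateral), rows along axis 1, columns along axis 2
  (anterior to posterior).
* A bounding box is six floats: relative center ``(c0, c1, c2)`` and
  relative size ``(s0, s1, s2)`` in the same axis order, where voxel values
  are divided by the axis length (number of voxels, 0-based indices).
* Box size is computed literally as ``max_index - min_index`` per axis, so a
  single-voxel structure has size 0 — a documented degenerate that the loss
  layer guards with an epsilon.  Cropping, by contrast, uses the inclusive
  voxel span (``max - min + 1``) so no structure voxel is lost.

The "5% margin" used when cropping to the meniscal region is interpreted
per axis as a fraction of the cropped extent itself (scale-free), and crop
shapes are rounded to the nearest multiple of 16 (half-up, floor 16) so the
encoders' stride pyramid divides them cleanly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "Box3D", "NormalizationStats", "minmax_normalize", "standardize",
    "fit_stats", "box_from_mask", "crop_to_rois", "training_crop_shape",
    "resample_trilinear", "resample_nearest", "union_extent_voxels",
]


@dataclass(frozen=True)
class Box3D:
    """Axis-aligned 3D box: relative center and relative size, 6 values."""

    center: tuple
    size: tuple

    def __post_init__(self):
        if len(self.center) != 3 or len(self.size) != 3:
            raise ValueError("center and size must be length-3")
        object.__setattr__(self, "center", tuple(float(v) for v in self.center))
        object.__setattr__(self, "size", tuple(float(v) for v in self.size))
        if not all(0.0 <= c <= 1.0 for c in self.center):
            raise ValueError(f"relative center out of [0,1]: {self.center}")
        if not all(0.0 <= s <= 1.0 for s in self.size):
            raise ValueError(f"relative size out of [0,1]: {self.size}")

    def to_array(self) -> np.ndarray:
        return np.array(self.center + self.size, dtype=np.float64)

    @classmethod
    def from_array(cls, values) -> "Box3D":
        values = np.asarray(values, dtype=np.float64).reshape(6)
        return cls(center=tuple(values[:3]), size=tuple(values[3:]))

    def corners(self) -> tuple:
        """(lo, hi) relative corner coordinates."""
        c, s = np.array(self.center), np.array(self.size)
        return c - s / 2.0, c + s / 2.0

    def voxel_bounds(self, shape) -> tuple:
        """Back-convert to (min_index, max_index) arrays on a given grid."""
        n = np.asarray(shape, dtype=np.float64)
        c = np.array(self.center) * n
        s = np.array(self.size) * n
        lo = c - s / 2.0
        hi = c + s / 2.0
        return lo, hi


@dataclass(frozen=True)
class NormalizationStats:
    """Pooled mean/sd of the (min-max normalised) training population."""

    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def to_json(self) -> str:
        return json.dumps({"mu": self.mu, "sigma": self.sigma})

    @classmethod
    def from_json(cls, text: str) -> "NormalizationStats":
        d = json.loads(text)
        return cls(mu=float(d["mu"]), sigma=float(d["sigma"]))


def minmax_normalize(image: np.ndarray) -> np.ndarray:
    """Affinely rescale intensities to [0, 1]."""
    image = np.asarray(image, dtype=np.float64)
    lo = image.min()
    hi = image.max()
    if hi == lo:
        raise ValueError("constant image: min-max normalization is degenerate")
    return ((image - lo) / (hi - lo)).astype(np.float32)


def standardize(image: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Voxel-wise (v - mu) / sigma with population statistics."""
    return ((np.asarray(image, dtype=np.float32) - stats.mu) / stats.sigma).astype(np.float32)


def fit_stats(training_volumes: list) -> NormalizationStats:
    """Pooled mean and (population) sd over all voxels of all training volumes."""
    if len(training_volumes) == 0:
        raise ValueError("need at least one training volume")
    n = 0
    total = 0.0
    total_sq = 0.0
    for vol in training_volumes:
        v = np.asarray(vol, dtype=np.float64)
        n += v.size
        total += v.sum()
        total_sq += (v * v).sum()
    mu = total / n
    var = total_sq / n - mu * mu
    if var <= 0:
        raise ValueError("zero pooled variance across training volumes")
    return NormalizationStats(mu=float(mu), sigma=float(np.sqrt(var)))


def box_from_mask(mask: np.ndarray, structure_id: int) -> Box3D:
    """Bounding box of one labelled structure, as relative center + size.

    Per-axis minimum and maximum voxel indices of the structure are queried;
    center = (max - min)/2 + min and size = max - min, both divided by the
    axis length.
    """
    mask = np.asarray(mask)
    coords = np.nonzero(mask == structure_id)
    if coords[0].size == 0:
        raise ValueError(f"structure {structure_id} absent from mask")
    center = []
    size = []
    for axis in range(3):
        lo = int(coords[axis].min())
        hi = int(coords[axis].max())
        n = mask.shape[axis]
        center.append(((hi - lo) / 2.0 + lo) / n)
        size.append((hi - lo) / n)
    return Box3D(center=tuple(center), size=tuple(size))


def _margined_voxel_bounds(boxes, shape, margin: float) -> tuple:
    """Inclusive voxel bounds of the boxes' union, expanded by `margin`."""
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    n = np.asarray(shape, dtype=np.float64)
    for box in boxes:
        c = np.array(box.center) * n
        s = np.array(box.size) * n
        lo = np.minimum(lo, c - s / 2.0)
        hi = np.maximum(hi, c + s / 2.0)
    hi = hi + 1.0  # inclusive span of the max voxel
    extent = hi - lo
    lo = lo - margin * extent
    hi = hi + margin * extent
    lo = np.maximum(np.floor(lo).astype(int), 0)
    hi = np.minimum(np.ceil(hi).astype(int), np.asarray(shape))
    if np.any(hi <= lo):
        raise ValueError("margined box union does not intersect the grid")
    return lo, hi


def union_extent_voxels(boxes, shape, margin: float) -> np.ndarray:
    """Per-axis voxel extent of the margined union of a pair of boxes."""
    lo, hi = _margined_voxel_bounds(boxes, shape, margin)
    return hi - lo


def resample_trilinear(volume: np.ndarray, target_shape) -> np.ndarray:
    """Trilinear resampling with corner-aligned index mapping.

    Target index t on an axis of T voxels samples source coordinate
    t*(S-1)/(T-1); a singleton target axis samples the source midpoint.
    """
    volume = np.asarray(volume, dtype=np.float32)
    src = np.asarray(volume.shape, dtype=np.float64)
    tgt = np.asarray(target_shape, dtype=int)
    if tuple(tgt) == volume.shape:
        return volume.copy()
    axes = []
    for s, t in zip(src, tgt):
        if t == 1:
            axes.append(np.array([(s - 1) / 2.0]))
        else:
            axes.append(np.arange(t) * (s - 1) / (t - 1))
    grid = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    out = ndimage.map_coordinates(volume, coords, order=1, mode="nearest")
    return out.reshape(tuple(tgt)).astype(np.float32)


def resample_nearest(volume: np.ndarray, target_shape) -> np.ndarray:
    """Nearest-neighbour resampling (for label masks), same index mapping
    as :func:`resample_trilinear`."""
    volume = np.asarray(volume)
    tgt = np.asarray(target_shape, dtype=int)
    if tuple(tgt) == volume.shape:
        return volume.copy()
    idx = []
    for s, t in zip(volume.shape, tgt):
        if t == 1:
            idx.append(np.array([int(round((s - 1) / 2.0))]))
        else:
            idx.append(np.round(np.arange(t) * (s - 1) / (t - 1)).astype(int))
    return volume[np.ix_(*idx)]


def crop_to_rois(image: np.ndarray, boxes, margin: float, target_shape) -> np.ndarray:
    """Crop the margined union of both meniscal boxes and resample.

    The union extent of the box pair is expanded by ``margin`` per axis,
    clamped to the grid, cropped, and trilinearly resampled to
    ``target_shape``.
    """
    image = np.asarray(image)
    lo, hi = _margined_voxel_bounds(boxes, image.shape, margin)
    cropped = image[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return resample_trilinear(cropped, target_shape)


def _round_to_16(extent: float) -> int:
    """Nearest multiple of 16 (half rounds up), never below 16."""
    return max(16, int(np.floor(extent / 16.0 + 0.5)) * 16)


def training_crop_shape(box_pairs: list, shape, margin: float) -> tuple:
    """Fixed crop shape for a training set: per-axis maximum margined union
    extent over all box pairs, rounded to the closest multiple of 16."""
    if len(box_pairs) == 0:
        raise ValueError("empty training set")
    max_extent = np.zeros(3)
    for pair in box_pairs:
        max_extent = np.maximum(max_extent, union_extent_voxels(pair, shape, margin))
    return tuple(_round_to_16(e) for e in max_extent)
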