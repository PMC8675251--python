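"""Gradient saliency maps and the augmentation-averaged SmoothGrad variant.

A saliency map is the derivative of one sub-region's pre-sigmoid logit with
respect to the input volume, obtained by back-propagation through the
network; the pre-sigmoid logit is used because the saturating sigmoid would
wash the gradients out.  Maps are reported as gradient magnitudes by
default (signed maps are available via a flag).

SmoothGrad averages the maps of several independently augmented copies of
the input (noise, intensity scaling, small in-plane rotations, horizontal
flips, each applied with 50% probability).  Before averaging, each map is
transformed back onto the original voxel grid: rotations are inverted and
flips undone — and because a flip mirrors the anterior-posterior axis, the
targeted sub-region index is mirrored for flipped copies so every map
explains the same anatomical region.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .augment import FLIP_LABEL_ORDER
from .autodiff import Tensor
from .nets import MultiTaskModel

__all__ = ["SaliencyConfig", "gradient_map", "smoothgrad", "export_overlay"]


@dataclass(frozen=True)
class SaliencyConfig:
    n_augmentations: int = 20
    per_augmentation_prob: float = 0.5
    noise_mean: float = 0.1
    noise_sd: float = 0.5
    rotation_range: float = 5.0
    intensity_range: tuple = (0.9, 1.1)
    flip_prob: float = 0.5
    signed: bool = False

    def __post_init__(self):
        if self.n_augmentations < 1:
            raise ValueError("n_augmentations must be >= 1")
        if not 0.0 <= self.per_augmentation_prob <= 1.0:
            raise ValueError("per_augmentation_prob must be in [0, 1]")


def gradient_map(model: MultiTaskModel, image: np.ndarray,
                 target_subregion: int, signed: bool = False) -> np.ndarray:
    """d(logit_c)/d(input) for one sub-region, on the input grid.

    `image` is a prepared (standardised, input-shaped) volume; the model is
    evaluated in eval mode so the map is deterministic.
    """
    if not 0 <= int(target_subregion) < 6:
        raise ValueError("target_subregion must be in 0..5")
    model.eval()
    x = Tensor(np.asarray(image, dtype=np.float32)[None, None], requires_grad=True)
    out = model.logits(x)
    cls_logits = out[0] if isinstance(out, tuple) else out
    cls_logits[0, int(target_subregion)].backward()
    grad = x.grad[0, 0]
    return grad if signed else np.abs(grad)


def smoothgrad(model: MultiTaskModel, image: np.ndarray, cfg: SaliencyConfig,
               rng: np.random.Generator, target_subregion: int = 0) -> np.ndarray:
    """Augmentation-averaged saliency volume on the original grid."""
    image = np.asarray(image, dtype=np.float32)
    maps = np.zeros(image.shape, dtype=np.float64)
    for _ in range(cfg.n_augmentations):
        aug = image
        flipped = False
        angle = 0.0
        if rng.random() < cfg.flip_prob:
            aug = aug[:, :, ::-1].copy()
            flipped = True
        if cfg.rotation_range > 0 and rng.random() < cfg.per_augmentation_prob:
            angle = float(rng.uniform(-cfg.rotation_range, cfg.rotation_range))
            aug = ndimage.rotate(aug, angle, axes=(1, 2), reshape=False,
                                 order=1, mode="nearest")
        if rng.random() < cfg.per_augmentation_prob:
            aug = aug * float(rng.uniform(*cfg.intensity_range))
        if cfg.noise_sd > 0 and rng.random() < cfg.per_augmentation_prob:
            aug = aug + rng.normal(cfg.noise_mean, cfg.noise_sd,
                                   size=aug.shape).astype(np.float32)
        target = FLIP_LABEL_ORDER[target_subregion] if flipped else target_subregion
        m = gradient_map(model, aug, target, signed=cfg.signed)
        # invert geometric transforms so all maps share the original grid
        if angle != 0.0:
            m = ndimage.rotate(m, -angle, axes=(1, 2), reshape=False,
                               order=1, mode="nearest")
        if flipped:
            m = m[:, :, ::-1]
        maps += m
    return (maps / cfg.n_augmentations).astype(np.float32)


def export_overlay(image: np.ndarray, saliency: np.ndarray, slice_index: int,
                   out_path) -> Path:
    """Write one sagittal slice as grayscale with a heat overlay (PNG).

    The saliency volume is normalised per-volume to [0, 1] for display; an
    all-zero map yields the plain grayscale slice.
    """
    image = np.asarray(image)
    saliency = np.asarray(saliency)
    if image.shape != saliency.shape:
        raise ValueError("image and saliency map shapes differ")
    if not 0 <= slice_index < image.shape[0]:
        raise ValueError("slice index out of range")
    peak = saliency.max()
    heat = saliency / peak if peak > 0 else np.zeros_like(saliency)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    sl_img = image[slice_index]
    sl_heat = heat[slice_index]
    fig, ax = plt.subplots(figsize=(4, 4 * sl_img.shape[0] / sl_img.shape[1]))
    ax.imshow(sl_img, cmap="gray", interpolation="nearest")
    ax.imshow(sl_heat, cmap="inferno", alpha=0.5 * sl_heat, interpolation="nearest")
    ax.axis("off")
    fig.tight_layout(pad=0)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def save_saliency_nifti(saliency: np.ndarray, out_path, spacing=(1.0, 1.0, 1.0)):
    """Write the 3D saliency volume as NIfTI."""
    import nibabel as nib

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    aff = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(saliency, dtype=np.float32), aff), out_path)
    return out_path
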