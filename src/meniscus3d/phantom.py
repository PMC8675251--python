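"""Synthetic volumetric knee phantoms with ground-truth masks, boxes and labels.

Each phantom emulates, at a configurable grid size, the geometry a sagittal
knee MRI presents to the detection task: two crescent-shaped "meniscus"
structures — medial in the lower half of the slice axis, lateral in the
upper half — each divided into anterior / body / posterior thirds along the
anterior-posterior (column) axis of the structure's own bounding box.  A
planted "tear" is a thin hyper-intense sheet of voxels lying entirely inside
the flagged sub-region.  The background carries a smooth random texture plus
white noise, and intensities are produced in arbitrary units so that min-max
normalisation downstream is exercised non-trivially.

Geometric thirds stand in for the anatomical sub-region definitions used by
expert readings of real scans; they are unambiguous and exactly testable but
make no claim of anatomical equivalence.

Everything is driven by a single integer seed: the same seed yields
bit-identical phantoms and cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import box_from_mask

__all__ = [
    "SUBREGION_NAMES", "MEDIAL", "LATERAL", "PhantomSpec", "PhantomSample",
    "generate_phantom", "generate_cohort", "subregion_mask",
    "save_sample_nifti", "load_sample_nifti", "write_cohort", "read_manifest",
    "MANIFEST_COLUMNS",
]

#: label order: medial anterior-horn, body, posterior-horn, then lateral
SUBREGION_NAMES = ("mm_ah", "mm_b", "mm_ph", "lm_ah", "lm_b", "lm_ph")

#: mask labels (0 = background)
MEDIAL, LATERAL = 1, 2

_BOX_COLUMNS = tuple(
    f"{side}_{kind}{ax}" for side in ("mm", "lm")
    for kind in ("c", "s") for ax in range(3)
)
MANIFEST_COLUMNS = ("id",) + SUBREGION_NAMES + _BOX_COLUMNS


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    Intensities are in arbitrary units (a.u.): background plateau ~120,
    meniscal tissue ~420, tears offset by ``lesion_contrast`` above tissue.
    Defaults describe an easy, high-contrast phantom.
    """

    grid_shape: tuple = (32, 64, 64)
    voxel_spacing: tuple = (1.0, 1.0, 1.0)
    tear_flags: tuple = (0, 0, 0, 0, 0, 0)
    lesion_contrast: float = 300.0
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(g) < 16 for g in self.grid_shape):
            raise ValueError("all grid dimensions must be >= 16")
        object.__setattr__(self, "grid_shape", tuple(int(g) for g in self.grid_shape))
        object.__setattr__(self, "voxel_spacing", tuple(float(v) for v in self.voxel_spacing))
        flags = tuple(int(f) for f in self.tear_flags)
        if len(flags) != 6 or any(f not in (0, 1) for f in flags):
            raise ValueError("tear_flags must be six binary values")
        object.__setattr__(self, "tear_flags", flags)
        if self.lesion_contrast <= 0:
            raise ValueError("lesion_contrast must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class PhantomSample:
    """A generated phantom: image, label mask, tear labels and both boxes."""

    image: np.ndarray
    mask: np.ndarray
    labels: np.ndarray                      # six binaries, SUBREGION_NAMES order
    boxes: tuple                            # (medial Box3D, lateral Box3D)
    spec: PhantomSpec | None = None
    sample_id: str = ""

    @property
    def spacing(self) -> tuple:
        return self.spec.voxel_spacing if self.spec is not None else (1.0, 1.0, 1.0)


_BG_BASE = 120.0
_BG_TEXTURE_AMP = 40.0
_TISSUE = 420.0


def _crescent_mask(shape, slice_range, center_rc, radii) -> np.ndarray:
    """C-shaped (annulus-sector) structure extruded over a slice range,
    with tapered radii toward the edge slices."""
    z0, z1 = slice_range
    r_inner, r_outer = radii
    rows = np.arange(shape[1], dtype=np.float64)[:, None]
    cols = np.arange(shape[2], dtype=np.float64)[None, :]
    dr = rows - center_rc[0]
    dc = cols - center_rc[1]
    rho = np.hypot(dr, dc)
    theta = np.degrees(np.arctan2(dr, dc))  # 0 deg = +col (posterior)
    # keep everything except a wedge opening toward +row, so both the
    # anterior (|theta| near 180) and posterior (theta near 0) ends exist
    wedge = (theta > 40.0) & (theta < 140.0)
    mask = np.zeros(shape, dtype=bool)
    nz = z1 - z0
    for i, z in enumerate(range(z0, z1)):
        # elliptical taper of the annulus toward the first/last slice
        u = (i + 0.5) / nz * 2.0 - 1.0
        taper = float(np.sqrt(max(0.15, 1.0 - u * u)))
        r_in = r_inner * (0.75 + 0.25 * taper)
        r_out = r_outer * (0.55 + 0.45 * taper)
        mask[z] = (rho >= r_in) & (rho <= r_out) & ~wedge
    return mask


def subregion_mask(mask: np.ndarray, subregion: int) -> np.ndarray:
    """Boolean support of one of the six sub-regions.

    Sub-regions are thirds of equal extent along the anterior-posterior
    (column) axis of the structure's own bounding box; index order follows
    SUBREGION_NAMES.
    """
    if not 0 <= subregion < 6:
        raise ValueError("subregion index must be in 0..5")
    structure = MEDIAL if subregion < 3 else LATERAL
    third = subregion % 3
    support = mask == structure
    if not support.any():
        raise ValueError(f"structure {structure} absent from mask")
    cols = np.nonzero(support.any(axis=(0, 1)))[0]
    lo, hi = cols.min(), cols.max() + 1
    edges = np.round(lo + (hi - lo) * np.arange(4) / 3.0).astype(int)
    sel = np.zeros_like(support)
    sel[:, :, edges[third]:edges[third + 1]] = True
    return support & sel


def _plant_lesion(image: np.ndarray, mask: np.ndarray, subregion: int,
                  contrast: float) -> np.ndarray:
    """Add a thin bright sheet inside the sub-region; returns lesion support."""
    region = subregion_mask(mask, subregion)
    rows = np.nonzero(region)[1]
    r_med = int(np.median(rows))
    sheet = np.zeros_like(region)
    half = 1
    while True:
        sheet[:, max(0, r_med - half):r_med + half + 1, :] = True
        lesion = region & sheet
        if lesion.any():
            break
        half += 1  # widen until the sheet meets the region (always terminates)
    image[lesion] += contrast
    return lesion


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Deterministically generate one phantom from its spec."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    ns, nr, nc = shape

    # smooth background texture (low-pass filtered white noise)
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=4.0)
    peak = np.abs(texture).max()
    if peak > 0:
        texture = texture / peak
    image = _BG_BASE + _BG_TEXTURE_AMP * texture

    # two crescents: medial in the lower slice-index half, lateral upper
    mask = np.zeros(shape, dtype=np.int16)
    in_plane = min(nr, nc)
    r_outer = 0.30 * in_plane
    r_inner = 0.16 * in_plane
    half_thick = max(4, int(round(ns * 0.30)))
    for structure, z_center_frac in ((MEDIAL, 0.27), (LATERAL, 0.73)):
        jitter = rng.uniform(-1.5, 1.5, size=2)
        rj = rng.uniform(-0.8, 0.8)
        zc = int(round(ns * z_center_frac + rng.uniform(-1.0, 1.0)))
        z0 = max(0, zc - half_thick // 2)
        z1 = min(ns, z0 + half_thick)
        center_rc = (nr / 2.0 + jitter[0], nc / 2.0 + jitter[1])
        crescent = _crescent_mask(shape, (z0, z1), center_rc,
                                  (r_inner + rj, r_outer + rj))
        crescent &= mask == 0  # halves are disjoint by construction anyway
        mask[crescent] = structure
    image[mask > 0] = _TISSUE

    labels = np.asarray(spec.tear_flags, dtype=np.int8)
    for sub in range(6):
        if labels[sub]:
            _plant_lesion(image, mask, sub, spec.lesion_contrast)

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=shape)

    boxes = (box_from_mask(mask, MEDIAL), box_from_mask(mask, LATERAL))
    return PhantomSample(image=image.astype(np.float32), mask=mask,
                         labels=labels, boxes=boxes, spec=spec)


def generate_cohort(n: int, prevalence, seed: int,
                    grid_shape=(32, 64, 64), voxel_spacing=(1.0, 1.0, 1.0),
                    lesion_contrast: float = 300.0, noise_sd: float = 20.0):
    """Generate `n` phantoms with independent Bernoulli tear flags.

    Returns ``(samples, manifest)`` where the manifest is a DataFrame with
    one row per sample: id, the six labels, and the twelve box values
    (medial center/size then lateral center/size, axis order slice,row,col).
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    prevalence = np.broadcast_to(np.asarray(prevalence, dtype=np.float64), (6,))
    if np.any((prevalence < 0) | (prevalence > 1)):
        raise ValueError("prevalence values must be in [0, 1]")
    root = np.random.SeedSequence(seed)
    samples = []
    rows = []
    for i, child in enumerate(root.spawn(n)):
        child_rng = np.random.default_rng(child)
        flags = (child_rng.random(6) < prevalence).astype(int)
        sample_seed = int(child_rng.integers(2 ** 31))
        spec = PhantomSpec(grid_shape=tuple(grid_shape),
                           voxel_spacing=tuple(voxel_spacing),
                           tear_flags=tuple(flags),
                           lesion_contrast=lesion_contrast,
                           noise_sd=noise_sd, seed=sample_seed)
        sample = generate_phantom(spec)
        sample.sample_id = f"phantom_{i:04d}"
        samples.append(sample)
        rows.append([sample.sample_id] + list(map(int, sample.labels))
                    + list(sample.boxes[0].to_array()) + list(sample.boxes[1].to_array()))
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    return samples, manifest


# ---------------------------------------------------------------------------
# NIfTI / CSV round-trip
# ---------------------------------------------------------------------------

_MANIFEST_HEADER = (
    "# meniscus3d cohort manifest\n"
    "# axis order: (slice, row, col); medial = lower slice-index half, "
    "lateral = upper half; sub-regions = thirds along the col "
    "(anterior-posterior) axis of each structure's bounding box\n"
    "# box columns: relative center c0..c2 then relative size s0..s2, "
    "medial (mm) first then lateral (lm)\n"
)


def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def save_sample_nifti(sample: PhantomSample, out_dir, sample_id: str | None = None):
    """Write image and mask as .nii.gz; returns the two paths."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = sample_id or sample.sample_id or "phantom"
    aff = _affine(sample.spacing)
    img_path = out_dir / f"{sid}_image.nii.gz"
    mask_path = out_dir / f"{sid}_mask.nii.gz"
    nib.save(nib.Nifti1Image(sample.image.astype(np.float32), aff), img_path)
    nib.save(nib.Nifti1Image(sample.mask.astype(np.int16), aff), mask_path)
    return img_path, mask_path


def load_sample_nifti(img_path, mask_path=None) -> PhantomSample:
    """Read a volume (and optional mask) back into a PhantomSample shell."""
    import nibabel as nib

    img = nib.load(str(img_path))
    image = np.asarray(img.dataobj, dtype=np.float32)
    mask = None
    boxes = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj).astype(np.int16)
        boxes = (box_from_mask(mask, MEDIAL), box_from_mask(mask, LATERAL))
    spacing = tuple(float(v) for v in img.header.get_zooms()[:3])
    spec = PhantomSpec(grid_shape=image.shape, voxel_spacing=spacing)
    return PhantomSample(image=image, mask=mask, labels=np.zeros(6, dtype=np.int8),
                         boxes=boxes, spec=spec)


def write_cohort(samples, manifest: pd.DataFrame, out_dir) -> Path:
    """Write all volumes plus the manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sample in samples:
        save_sample_nifti(sample, out_dir)
    path = out_dir / "manifest.csv"
    with open(path, "w") as fh:
        fh.write(_MANIFEST_HEADER)
        manifest.to_csv(fh, index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
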