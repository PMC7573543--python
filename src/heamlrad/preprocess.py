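"""Image/mask IO, slice selection, spline resampling, gray-level discretization.

Coordinate convention: row-major 2-D arrays, 0-based indices; physical pixel
spacing (row_mm, col_mm) carried as metadata. Images travel as NIfTI by
default, with a dependency-light 16-bit PNG dialect (spacing in a JSON
sidecar) for quick inspection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image
from scipy import ndimage


class ShapeMismatchError(ValueError):
    pass


class EmptyMaskError(ValueError):
    pass


@dataclass
class PhantomImage:
    pixels: np.ndarray  # 2-D float grid (or 3-D stack before slice selection)
    spacing: tuple[float, float]
    modality: str = "CT"

    def validate(self) -> None:
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be > 0")


@dataclass
class RoiMask:
    data: np.ndarray  # boolean grid, same shape as the image

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class DiscretizedRoi:
    """Integer grid: 0 outside the mask, 1..n_bins inside."""

    levels: np.ndarray
    n_bins: int
    channel: str = "original"

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    def in_mask(self) -> np.ndarray:
        return self.levels[self.levels > 0]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def save_case(img: PhantomImage, mask: RoiMask, stem: Path,
              image_format: str = "nii") -> tuple[Path, Path]:
    """Write an image/mask pair; returns the two paths.

    ``nii``: float64 NIfTI with spacing in the affine (deterministic bytes).
    ``png``: 16-bit grayscale PNG (intensities rounded to integers) plus a
    ``<stem>.spacing.json`` sidecar; mask as 8-bit PNG.
    """
    stem = Path(stem)
    if image_format == "nii":
        affine = np.diag([img.spacing[0], img.spacing[1], 1.0, 1.0])
        ipath, mpath = stem.with_suffix(".nii"), Path(str(stem) + "_mask.nii")
        nib.save(nib.Nifti1Image(np.asarray(img.pixels, dtype=np.float64), affine), ipath)
        nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), mpath)
    elif image_format == "png":
        ipath, mpath = stem.with_suffix(".png"), Path(str(stem) + "_mask.png")
        arr = np.round(img.pixels).astype(np.int64)
        if arr.min() < 0 or arr.max() > 65535:
            raise ValueError("PNG dialect requires intensities in [0, 65535]")
        Image.fromarray(arr.astype(np.uint16)).save(ipath)
        Image.fromarray((mask.data.astype(np.uint8) * 255)).save(mpath)
        stem.with_suffix(".spacing.json").write_text(
            json.dumps({"spacing": list(img.spacing), "modality": img.modality})
        )
    else:
        raise ValueError(f"unknown image format {image_format!r}")
    return ipath, mpath


def load_case(image_path: str | Path, mask_path: str | Path) -> tuple[PhantomImage, RoiMask]:
    """Read an aligned image/mask pair written by :func:`save_case`."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    if image_path.suffix == ".png":
        pixels = np.asarray(Image.open(image_path), dtype=float)
        maskarr = np.asarray(Image.open(mask_path)) > 0
        sidecar = image_path.with_suffix(".spacing.json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {"spacing": [1.0, 1.0]}
        spacing = tuple(meta["spacing"])
        modality = meta.get("modality", "CT")
    else:
        nimg, nmask = nib.load(image_path), nib.load(mask_path)
        pixels = np.asarray(nimg.dataobj, dtype=float)
        maskarr = np.asarray(nmask.dataobj) > 0
        zooms = nimg.header.get_zooms()
        spacing = (float(zooms[0]), float(zooms[1]))
        modality = "CT"
    pixels = np.squeeze(pixels)
    maskarr = np.squeeze(maskarr)
    if pixels.shape != maskarr.shape:
        raise ShapeMismatchError(f"image {pixels.shape} vs mask {maskarr.shape}")
    if not maskarr.any():
        raise EmptyMaskError(f"mask {mask_path} has no foreground")
    return PhantomImage(pixels, spacing), RoiMask(maskarr)


# ---------------------------------------------------------------------------
# Slice selection / resampling / discretization
# ---------------------------------------------------------------------------

def select_slice(volume: PhantomImage, mask_volume: RoiMask) -> tuple[PhantomImage, RoiMask]:
    """Pick the analysis slice: the one with the largest in-mask area.

    3-D stacks are indexed (slice, row, col); ties go to the lowest slice
    index. 2-D input passes through unchanged.
    """
    if volume.pixels.ndim == 2:
        return volume, mask_volume
    areas = mask_volume.data.reshape(mask_volume.data.shape[0], -1).sum(axis=1)
    if areas.sum() == 0:
        raise EmptyMaskError("mask volume is empty")
    k = int(np.argmax(areas))  # argmax returns the first maximum
    return (
        PhantomImage(volume.pixels[k], volume.spacing, volume.modality),
        RoiMask(mask_volume.data[k]),
    )


def resample(
    image: PhantomImage,
    mask: RoiMask,
    target_spacing: float = 1.0,
) -> tuple[PhantomImage, RoiMask]:
    """Resample image (cubic spline) and mask (nearest neighbour) onto an
    isotropic grid of ``target_spacing`` mm.

    Output pixel k sits at physical position k * target_spacing along each
    axis (corner-aligned grids). Identity when spacing already matches.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be > 0")
    if all(abs(s - target_spacing) < 1e-9 for s in image.spacing):
        return image, mask
    nrows, ncols = image.pixels.shape
    out_shape = (
        int(np.floor((nrows - 1) * image.spacing[0] / target_spacing)) + 1,
        int(np.floor((ncols - 1) * image.spacing[1] / target_spacing)) + 1,
    )
    rr = np.arange(out_shape[0]) * target_spacing / image.spacing[0]
    cc = np.arange(out_shape[1]) * target_spacing / image.spacing[1]
    coords = np.meshgrid(rr, cc, indexing="ij")
    newpix = ndimage.map_coordinates(image.pixels, coords, order=3, mode="mirror")
    newmask = ndimage.map_coordinates(
        mask.data.astype(np.uint8), coords, order=0, mode="constant"
    ).astype(bool)
    if not newmask.any():
        raise EmptyMaskError("mask vanished under resampling")
    return (
        PhantomImage(newpix, (target_spacing, target_spacing), image.modality),
        RoiMask(newmask),
    )


def discretize(
    image_pixels: np.ndarray,
    mask: np.ndarray,
    n_bins: int = 64,
    channel: str = "original",
) -> DiscretizedRoi:
    """Equal-width binning of in-mask intensities over their observed range.

    bin(x) = floor((x - min) / (max - min) * n_bins) + 1, with x = max mapped
    to n_bins. A constant ROI maps every in-mask pixel to level 1. Out-of-mask
    pixels are exactly 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not mask.any():
        raise EmptyMaskError("cannot discretize an empty ROI")
    vals = np.asarray(image_pixels, dtype=float)
    lo, hi = vals[mask].min(), vals[mask].max()
    levels = np.zeros(vals.shape, dtype=np.int32)
    if hi > lo:
        binned = np.floor((vals[mask] - lo) / (hi - lo) * n_bins).astype(np.int32) + 1
        levels[mask] = np.minimum(binned, n_bins)
    else:
        levels[mask] = 1
    return DiscretizedRoi(levels=levels, n_bins=n_bins, channel=channel)
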