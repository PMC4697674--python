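"""Reading and writing images and label maps.

NIfTI volumes/slices go through nibabel (affine and header preserved);
8/16-bit PNG/TIFF grayscale images go through imageio.  Masks follow the
nonzero-is-foreground convention.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .image import GrayImage

__all__ = ["ImageMeta", "read_gray", "read_mask", "write_labels", "write_gray"]


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


@dataclasses.dataclass
class ImageMeta:
    """Carrier for NIfTI affine/header so outputs can mirror the input."""

    affine: Optional[np.ndarray] = None
    header: Optional[object] = None


def read_gray(path: str | Path, mask_path: str | Path | None = None) -> tuple[GrayImage, ImageMeta]:
    """Load a grayscale image (NIfTI or PNG/TIFF), optionally with a mask."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        vol = nib.load(str(path))
        data = np.squeeze(np.asarray(vol.dataobj, dtype=np.float64))
        spacing = tuple(float(z) for z in vol.header.get_zooms()[: data.ndim])
        meta = ImageMeta(affine=vol.affine, header=vol.header)
    else:
        data = np.asarray(iio.imread(path), dtype=np.float64)
        if data.ndim == 3 and data.shape[-1] in (3, 4):
            raise ValueError(f"{path} is not single-channel grayscale")
        spacing = None
        meta = ImageMeta()
    mask = read_mask(mask_path) if mask_path is not None else None
    return GrayImage(pixels=data, mask=mask, spacing=spacing), meta


def read_mask(path: str | Path) -> np.ndarray:
    """Load a mask; any nonzero value counts as foreground."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        data = np.squeeze(np.asarray(nib.load(str(path)).dataobj))
    else:
        data = np.asarray(iio.imread(path))
    return data != 0


def write_labels(path: str | Path, labels: np.ndarray, meta: ImageMeta | None = None) -> None:
    """Write an integer label map as NIfTI or 8-bit PNG/TIFF."""
    path = Path(path)
    if _is_nifti(path):
        affine = meta.affine if meta is not None and meta.affine is not None else np.eye(4)
        nib.save(nib.Nifti1Image(labels.astype(np.int16), affine), str(path))
    else:
        if labels.max() > 255:
            raise ValueError("more than 255 labels cannot be stored as 8-bit PNG")
        iio.imwrite(path, labels.astype(np.uint8))


def write_gray(path: str | Path, pixels: np.ndarray, meta: ImageMeta | None = None) -> None:
    """Write a grayscale image as NIfTI (float) or 16-bit PNG/TIFF."""
    path = Path(path)
    if _is_nifti(path):
        affine = meta.affine if meta is not None and meta.affine is not None else np.eye(4)
        nib.save(nib.Nifti1Image(pixels.astype(np.float32), affine), str(path))
    else:
        scaled = np.clip(np.round(pixels), 0, np.iinfo(np.uint16).max)
        iio.imwrite(path, scaled.astype(np.uint16))
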