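"""Raster and mask IO.

Images are held internally as 2-D float64 arrays in (row, col) order, row 0
at top, on their native intensity scale (no rescaling to [0, 1]: every
stage of the model is covariant in intensity and the Gaussian kernel width
is defined in pixel units).  Masks are 2-D bool arrays, written as 0/255
8-bit PNG.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import UsageError

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_grayscale(
    path: str | Path,
    *,
    luminance: bool = False,
    slice_index: int | None = None,
) -> np.ndarray:
    """Load a 2-D grayscale image as float64, preserving native values.

    Parameters
    ----------
    path
        PNG, TIFF, or NIfTI (.nii/.nii.gz) file.
    luminance
        Convert multi-channel input by channel averaging; without it,
        multi-channel input is rejected.
    slice_index
        Index along the last axis for 3-D NIfTI volumes (required there).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read image: no such file {path}")
    if _is_nifti(path):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj)
        if vol.ndim == 3:
            if slice_index is None:
                raise UsageError(
                    f"{path} is a 3-D volume; a slice index is required"
                )
            if not 0 <= slice_index < vol.shape[2]:
                raise UsageError(
                    f"slice index {slice_index} outside volume depth {vol.shape[2]}"
                )
            arr = vol[:, :, slice_index]
        elif vol.ndim == 2:
            arr = vol
        else:
            raise UsageError(f"{path}: only 2-D or 3-D NIfTI supported")
    else:
        try:
            arr = iio.imread(path)
        except Exception as exc:  # imageio raises various backend errors
            raise IOError(f"cannot read image {path}: {exc}") from exc
        if arr.ndim == 3:
            if not luminance:
                raise UsageError(
                    f"{path} is multi-channel; pass luminance=True to average channels"
                )
            arr = arr.astype(np.float64).mean(axis=2)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise UsageError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise UsageError(f"{path}: image contains non-finite values")
    return arr


def write_grayscale(image: np.ndarray, path: str | Path) -> None:
    """Write a float image: .tif/.tiff as float32, .png rounded to uint16."""
    path = Path(path)
    image = np.asarray(image, dtype=np.float64)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, image.astype(np.float32))
        else:
            out = np.clip(np.rint(image), 0, 65535).astype(np.uint16)
            iio.imwrite(path, out)
    except OSError as exc:
        raise IOError(f"cannot write image {path}: {exc}") from exc


def read_mask(path: str | Path) -> np.ndarray:
    """Load a 0/255 PNG mask as a bool array (any value > 127 is True)."""
    return read_grayscale(path) > 127


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a bool mask as 8-bit PNG, 0 background / 255 foreground."""
    path = Path(path)
    mask = np.asarray(mask, dtype=bool)
    try:
        iio.imwrite(path, np.where(mask, 255, 0).astype(np.uint8))
    except OSError as exc:
        raise IOError(f"cannot write mask {path}: {exc}") from exc
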