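"""NIfTI volume/mask round-trip with spacing metadata.

Volumes are stored (z, y, x) in memory; NIfTI files are written (x, y, z) per
convention, with voxel spacing carried in the affine/zooms.  Integer data
round-trips exactly; real volumes are written as 32-bit floats.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

from .errors import FormatError


def write_volume(
    volume: np.ndarray, path: str, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> None:
    """Write a (z, y, x) volume as 32-bit float NIfTI with mm spacing."""
    data = np.asarray(volume, dtype=np.float32).transpose(2, 1, 0)
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    nib.save(nib.Nifti1Image(data, affine), path)


def read_volume(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns ((z, y, x) float array, (z, y, x) spacing)."""
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # malformed header / not NIfTI
        raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    return data.astype(np.float64).transpose(2, 1, 0), (float(zooms[2]), float(zooms[1]), float(zooms[0]))


def write_mask(
    mask: np.ndarray, path: str, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> None:
    """Write a binary (z, y, x) mask as unsigned 8-bit NIfTI."""
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise FormatError("mask values must be in {0, 1}")
    data = arr.astype(np.uint8).transpose(2, 1, 0)
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    nib.save(nib.Nifti1Image(data, affine), path)


def read_mask(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a binary NIfTI mask; rejects values outside {0, 1}."""
    vol, spacing = read_volume(path)
    if not np.isin(vol, (0, 1)).all():
        raise FormatError(f"{path}: mask values outside {{0, 1}}")
    return vol.astype(bool), spacing
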