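"""Thin NIfTI read/write helpers built on nibabel.

Arrays are kept in ``(slices, rows, cols)`` order (4D: trailing time axis) and
the affine is the diagonal spacing matrix, so voxel spacing survives a
round-trip exactly. Intensities are stored as float32, masks as uint8.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError


def spacing_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_volume(path: Path, data: np.ndarray, spacing: tuple[float, float, float]) -> None:
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, spacing_affine(spacing))
    img.header.set_zooms(tuple(spacing) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def read_volume(path: Path, mask: bool = False) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing NIfTI file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # corrupt or non-NIfTI content
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if mask:
        data = data.astype(bool)
    else:
        data = np.asarray(data, dtype=np.float64)
    return data, spacing
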