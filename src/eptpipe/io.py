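"""NIfTI-1 volume I/O.

All volumes are exchanged as NIfTI with an axis-aligned affine built from
the grid spacing; complex fields are stored as magnitude + phase pairs,
matching what a scanner exports.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .datatypes import VoxelGrid


class VolumeDimensionError(ValueError):
    """Volume is not a 3D image."""


class VolumeSpacingError(ValueError):
    """Volume header carries non-positive voxel spacing."""


def write_volume(
    path: str | Path, data: np.ndarray, grid: VoxelGrid, dtype=None
) -> Path:
    """Write a 3D volume as NIfTI-1 with spacing taken from the grid."""
    path = Path(path)
    data = np.asarray(data)
    if data.shape != grid.shape:
        raise ValueError(f"data shape {data.shape} does not match grid {grid.shape}")
    if dtype is not None:
        data = data.astype(dtype)
    affine = np.diag(list(grid.spacing_mm) + [1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(grid.spacing_mm)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    """Read a 3D NIfTI volume and its grid metadata.

    Raises ``FileNotFoundError`` for a missing file,
    :class:`VolumeDimensionError` for non-3D data, and
    :class:`VolumeSpacingError` for non-positive header spacing — distinct
    errors so callers can report precisely what is wrong with an input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeDimensionError(
            f"{path} has {data.ndim} dimensions; expected a 3D volume"
        )
    zooms = img.header.get_zooms()[:3]
    if any(not z > 0 for z in zooms):
        raise VolumeSpacingError(f"{path} header spacing {zooms} is not positive")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    grid = VoxelGrid(
        shape=data.shape, spacing_mm=tuple(float(z) for z in zooms), origin_mm=origin
    )
    return data, grid
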