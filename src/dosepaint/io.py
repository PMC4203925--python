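"""NIfTI I/O for SUV volumes, ROI masks and dose maps.

Volumes are written axis-aligned: the affine is ``diag(spacing)`` with the
origin in the translation column. On read, spacing is taken from the header
zooms and the origin from the affine translation; oblique orientations are
not interpreted (resampling is out of scope).

Masks are stored as 8-bit 0/1 volumes, scalar fields as float64.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np

from .core import DoseMap, ImageGrid, ROIMask, SUVVolume

__all__ = [
    "read_volume",
    "read_mask",
    "read_dose_map",
    "write_volume",
    "write_label_volume",
    "read_label_masks",
    "write_json",
]

Gridded = Union[SUVVolume, DoseMap, ROIMask]


def _grid_from_image(img: nib.Nifti1Image) -> ImageGrid:
    shape = tuple(int(s) for s in img.shape[:3])
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return ImageGrid(shape=shape, spacing=spacing, origin=origin)


def _load(path: os.PathLike | str) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    if img.ndim < 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {img.shape}")
    return img


def read_volume(path: os.PathLike | str) -> SUVVolume:
    """Read a NIfTI file as an SUV volume.

    Raises ``ValueError`` (from the container type) naming the number of
    offending voxels if the file contains negative values.
    """
    img = _load(path)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    return SUVVolume(grid=_grid_from_image(img), values=data)


def read_mask(path: os.PathLike | str, label: str = "") -> ROIMask:
    """Read a NIfTI file as a boolean ROI mask (nonzero voxels are members)."""
    img = _load(path)
    data = np.asarray(img.get_fdata())
    return ROIMask(grid=_grid_from_image(img), member=data != 0, label=label)


def read_dose_map(path: os.PathLike | str) -> DoseMap:
    """Read a NIfTI file as a dose map in Gy (prescription parameters are not
    stored in the image and come back unset)."""
    img = _load(path)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    return DoseMap(grid=_grid_from_image(img), dose_gy=data)


def write_volume(obj: Gridded, path: os.PathLike | str) -> None:
    """Write a volume, dose map or mask to NIfTI (.nii or .nii.gz).

    Masks go out as uint8 0/1; scalar fields as float64, so a write/read
    round trip preserves values bit-identically.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(obj, ROIMask):
        data = obj.member.astype(np.uint8)
    elif isinstance(obj, SUVVolume):
        data = obj.values.astype(np.float64)
    elif isinstance(obj, DoseMap):
        data = obj.dose_gy.astype(np.float64)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    img = nib.Nifti1Image(data, affine=obj.grid.affine)
    img.header.set_zooms(obj.grid.spacing)
    nib.save(img, str(path))


def write_label_volume(levels, path: os.PathLike | str) -> None:
    """Write a dose-level set as one integer label volume.

    Voxel values are 0 outside every level (GTV base / background) and
    ``k`` for voxels in level DPk (1-based).
    """
    grid = levels.grid
    labels = np.zeros(grid.shape, dtype=np.uint8)
    for k, mask in enumerate(levels.level_masks, start=1):
        labels[mask.member] = k
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(labels, affine=grid.affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def read_label_masks(path: os.PathLike | str) -> list[ROIMask]:
    """Read a label volume back into per-level masks (labels 1..max)."""
    img = _load(path)
    labels = np.asarray(img.get_fdata()).astype(np.int64)
    grid = _grid_from_image(img)
    n = int(labels.max())
    return [
        ROIMask(grid=grid, member=labels == k, label=f"DP{k}") for k in range(1, n + 1)
    ]


def write_json(payload: dict, path: os.PathLike | str) -> None:
    """Serialize a report dictionary to pretty-printed JSON."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
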