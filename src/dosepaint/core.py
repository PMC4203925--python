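"""Core gridded containers: image grid, SUV volume, ROI mask, dose map.

All arrays are indexed ``[i, j, k]`` in 0-based voxel coordinates; the third
index is the axial (slice) axis. World coordinates (mm) appear only in the
NIfTI headers written and read by :mod:`dosepaint.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "ImageGrid",
    "SUVVolume",
    "ROIMask",
    "DoseMap",
    "GridMismatchError",
    "assert_same_grid",
]

#: Tolerance (mm) for spacing/origin equality; absorbs float header round-trip noise.
GRID_TOL_MM = 1e-6


class GridMismatchError(ValueError):
    """Two gridded objects do not share shape, spacing, or origin."""


@dataclass(frozen=True)
class ImageGrid:
    """A regular 3D voxel grid.

    Parameters
    ----------
    shape
        Voxels per axis, all >= 1.
    spacing
        Voxel edge lengths in mm, all > 0.
    origin
        World coordinate (mm) of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("shape, spacing and origin must each have 3 components")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"all shape components must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def affine(self) -> np.ndarray:
        """Axis-aligned voxel-to-world affine (mm)."""
        aff = np.diag([*self.spacing, 1.0])
        aff[:3, 3] = self.origin
        return aff

    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))


def _as_grid(obj: Any) -> ImageGrid:
    if isinstance(obj, ImageGrid):
        return obj
    grid = getattr(obj, "grid", None)
    if grid is None:
        raise TypeError(f"object of type {type(obj).__name__} carries no ImageGrid")
    return grid


def assert_same_grid(a: Any, b: Any, tol_mm: float = GRID_TOL_MM) -> None:
    """Verify two gridded objects live on the same voxel grid.

    Passes silently when shapes are identical and spacing/origin agree within
    ``tol_mm``; otherwise raises :class:`GridMismatchError` naming the first
    differing field. Co-registration between grids is out of scope here — this
    only checks that it has already happened.
    """
    ga, gb = _as_grid(a), _as_grid(b)
    if ga.shape != gb.shape:
        raise GridMismatchError(f"shape mismatch: {ga.shape} vs {gb.shape}")
    if any(abs(x - y) > tol_mm for x, y in zip(ga.spacing, gb.spacing)):
        raise GridMismatchError(f"spacing mismatch: {ga.spacing} vs {gb.spacing}")
    if any(abs(x - y) > tol_mm for x, y in zip(ga.origin, gb.origin)):
        raise GridMismatchError(f"origin mismatch: {ga.origin} vs {gb.origin}")


@dataclass
class SUVVolume:
    """A 3D scalar field of standardized uptake values (dimensionless, >= 0)."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"value array shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        n_neg = int(np.count_nonzero(self.values < 0))
        if n_neg:
            raise ValueError(f"SUV values must be >= 0; {n_neg} voxel(s) are negative")

    def max_in(self, mask: "ROIMask") -> float:
        assert_same_grid(self, mask)
        if mask.voxel_count == 0:
            raise ValueError(f"mask {mask.label!r} is empty")
        return float(self.values[mask.member].max())

    def mean_in(self, mask: "ROIMask") -> float:
        assert_same_grid(self, mask)
        if mask.voxel_count == 0:
            raise ValueError(f"mask {mask.label!r} is empty")
        return float(self.values[mask.member].mean())


@dataclass
class ROIMask:
    """A boolean region of interest on a voxel grid (GTV, muscle, dose level...)."""

    grid: ImageGrid
    member: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=bool)
        if self.member.shape != self.grid.shape:
            raise ValueError(
                f"mask array shape {self.member.shape} != grid shape {self.grid.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.member))

    @property
    def volume_ccm(self) -> float:
        """Volume in cubic centimetres (1 ccm = 1000 mm^3)."""
        return self.voxel_count * self.grid.voxel_volume_mm3 / 1000.0


@dataclass
class DoseMap:
    """A voxelwise prescribed-dose field in Gy.

    Models the prescription, not delivered dose: zero outside the target,
    piecewise-constant level doses inside (unless smoothed by
    :func:`dosepaint.prescription.emulate_delivery`).
    """

    grid: ImageGrid
    dose_gy: np.ndarray
    params: Any = None
    level_doses_gy: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=np.float64)
        if self.dose_gy.shape != self.grid.shape:
            raise ValueError(
                f"dose array shape {self.dose_gy.shape} != grid shape {self.grid.shape}"
            )
        if np.any(self.dose_gy < 0):
            n = int(np.count_nonzero(self.dose_gy < 0))
            raise ValueError(f"dose must be >= 0 everywhere; {n} voxel(s) are negative")
        self.level_doses_gy = tuple(float(d) for d in self.level_doses_gy)

    def mean_in(self, mask: ROIMask) -> float:
        assert_same_grid(self, mask)
        return float(self.dose_gy[mask.member].mean())
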