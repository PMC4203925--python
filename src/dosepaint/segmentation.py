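"""Threshold-based segmentation of PET uptake into dose-escalation levels.

The high-risk sub-volume is the set of GTV voxels at or above a tracer-specific
absolute SUV cut-off. Three cut-off rules are supported, matching common PET
practice: a percentage of SUV_max within the GTV (the usual FDG rule), an
absolute SUV (used for hypoxia tracers with a calibrated threshold), and a
tumor-to-muscle ratio (when no absolute calibration exists, e.g. late
time-point scans).

The sub-volume is then partitioned into ``n_levels`` equal-width bins in
percent-of-max uptake; each bin is one dose level (DP1 low ... DPn high).
Bins are half-open ``[lower, upper)`` with the top bin closed at 100%, so a
voxel exactly at the cut-off belongs to DP1 and the max-uptake voxel to DPn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .core import ImageGrid, ROIMask, SUVVolume, assert_same_grid

__all__ = [
    "ThresholdSpec",
    "DoseLevelSet",
    "SubstructureValidity",
    "EmptySubvolumeWarning",
    "compute_cutoff",
    "build_dose_levels",
    "check_substructure_validity",
    "drop_degenerate_levels",
    "level_volume_table",
]

#: Axial (slice) axis: third voxel index, by convention throughout the package.
AXIAL_AXIS = 2

THRESHOLD_METHODS = ("percent_max", "absolute_suv", "tumor_to_muscle")


class EmptySubvolumeWarning(UserWarning):
    """The cut-off is at or above the GTV maximum: the high-risk sub-volume is empty."""


@dataclass(frozen=True)
class ThresholdSpec:
    """A cut-off rule for defining the high-risk sub-volume.

    ``value`` is a percent of SUV_max for ``percent_max`` (in (0, 100]),
    an absolute SUV for ``absolute_suv``, or a ratio for ``tumor_to_muscle``
    (both > 0).
    """

    method: str
    value: float

    def __post_init__(self) -> None:
        if self.method not in THRESHOLD_METHODS:
            raise ValueError(
                f"unknown threshold method {self.method!r}; expected one of {THRESHOLD_METHODS}"
            )
        v = float(self.value)
        object.__setattr__(self, "value", v)
        if self.method == "percent_max" and not (0 < v <= 100):
            raise ValueError(f"percent_max value must be in (0, 100], got {v}")
        if self.method in ("absolute_suv", "tumor_to_muscle") and v <= 0:
            raise ValueError(f"{self.method} value must be > 0, got {v}")


@dataclass
class DoseLevelSet:
    """An ordered partition of the high-risk sub-volume into dose levels.

    ``boundaries_pct`` holds ``n_levels + 1`` ascending bin edges in percent
    of SUV_max, from the cut-off percentage (SUV_c) up to 100. ``iso_pct``
    holds the bin midpoints (SUV_iso) used by the dose prescription.
    ``dropped_levels`` lists 1-based indices of levels removed as degenerate
    by :func:`drop_degenerate_levels`; their voxels were merged downward.
    """

    n_levels: int
    cutoff_suv: float
    cutoff_pct: float
    max_suv: float
    boundaries_pct: np.ndarray
    level_masks: list[ROIMask]
    iso_pct: np.ndarray
    dropped_levels: list[int] = field(default_factory=list)

    @property
    def grid(self) -> ImageGrid:
        return self.level_masks[0].grid

    def level_voxel_counts(self) -> list[int]:
        return [m.voxel_count for m in self.level_masks]

    def summary(self) -> dict:
        return {
            "n_levels": self.n_levels,
            "cutoff_suv": self.cutoff_suv,
            "cutoff_pct": self.cutoff_pct,
            "max_suv": self.max_suv,
            "boundaries_pct": [float(b) for b in self.boundaries_pct],
            "iso_pct": [float(i) for i in self.iso_pct],
            "level_volumes_ccm": [m.volume_ccm for m in self.level_masks],
            "dropped_levels": list(self.dropped_levels),
        }


@dataclass(frozen=True)
class SubstructureValidity:
    """Whether a substructure spans enough axial slices to be a real volume."""

    valid: bool
    axial_slices: int


def compute_cutoff(
    volume: SUVVolume,
    gtv: ROIMask,
    spec: ThresholdSpec,
    muscle: Optional[ROIMask] = None,
) -> float:
    """Convert a threshold rule into an absolute SUV cut-off.

    ``percent_max`` scales the GTV SUV_max; ``absolute_suv`` passes the value
    through; ``tumor_to_muscle`` multiplies the mean SUV over the muscle ROI
    (which is then required and non-empty).

    Emits :class:`EmptySubvolumeWarning` when the cut-off reaches or exceeds
    the GTV maximum, in which case thresholding yields an empty (or
    argmax-only, at exact equality) sub-volume.
    """
    assert_same_grid(volume, gtv)
    if gtv.voxel_count == 0:
        raise ValueError("GTV mask is empty")
    max_suv = volume.max_in(gtv)
    if spec.method == "percent_max":
        cutoff = spec.value / 100.0 * max_suv
    elif spec.method == "absolute_suv":
        cutoff = spec.value
    else:  # tumor_to_muscle
        if muscle is None or muscle.voxel_count == 0:
            raise ValueError("tumor_to_muscle threshold requires a non-empty muscle ROI")
        assert_same_grid(volume, muscle)
        cutoff = spec.value * volume.mean_in(muscle)
    if cutoff > max_suv or (cutoff == max_suv and spec.method != "percent_max"):
        warnings.warn(
            f"cut-off {cutoff:.4g} >= GTV SUV_max {max_suv:.4g}: empty high-risk sub-volume",
            EmptySubvolumeWarning,
            stacklevel=2,
        )
    return float(cutoff)


def build_dose_levels(
    volume: SUVVolume,
    gtv: ROIMask,
    cutoff_suv: float,
    n_levels: int = 5,
) -> DoseLevelSet:
    """Partition the high-risk sub-volume into equal-width uptake bins.

    Bin edges are equally spaced in percent-of-max between the cut-off
    percentage and 100. A voxel with uptake ``u`` (percent of max) lands in
    bin ``k`` iff ``boundaries[k] <= u < boundaries[k+1]``, with the top bin
    closed at 100 so the maximum voxel is always assigned. Assignment is
    restricted to the GTV.
    """
    assert_same_grid(volume, gtv)
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    if gtv.voxel_count == 0:
        raise ValueError("GTV mask is empty")
    max_suv = volume.max_in(gtv)
    if not cutoff_suv < max_suv:
        raise ValueError(
            f"empty high-risk sub-volume: cut-off {cutoff_suv:.4g} >= GTV SUV_max {max_suv:.4g}"
        )
    cutoff_pct = cutoff_suv / max_suv * 100.0
    boundaries = np.linspace(cutoff_pct, 100.0, n_levels + 1)
    iso = (boundaries[:-1] + boundaries[1:]) / 2.0

    pct = np.zeros(volume.grid.shape)
    pct[gtv.member] = volume.values[gtv.member] / max_suv * 100.0
    in_subvol = gtv.member & (volume.values >= cutoff_suv)
    # searchsorted over the interior edges gives the half-open binning with
    # the top bin absorbing u == 100.
    bin_idx = np.searchsorted(boundaries[1:-1], pct, side="right")

    masks = []
    for k in range(n_levels):
        mk = in_subvol & (bin_idx == k)
        masks.append(ROIMask(grid=volume.grid, member=mk, label=f"DP{k + 1}"))
    return DoseLevelSet(
        n_levels=n_levels,
        cutoff_suv=float(cutoff_suv),
        cutoff_pct=float(cutoff_pct),
        max_suv=max_suv,
        boundaries_pct=boundaries,
        level_masks=masks,
        iso_pct=iso,
    )


def check_substructure_validity(mask: ROIMask, axial_axis: int = AXIAL_AXIS) -> SubstructureValidity:
    """Flag substructures confined to at most one axial slice.

    A dose-level substructure present on a single CT slice is not a usable
    volume for plan optimization; such levels are dropped downstream.
    """
    if mask.voxel_count == 0:
        return SubstructureValidity(valid=False, axial_slices=0)
    axes = tuple(a for a in range(3) if a != axial_axis)
    slices = int(np.count_nonzero(mask.member.any(axis=axes)))
    return SubstructureValidity(valid=slices > 1, axial_slices=slices)


def drop_degenerate_levels(levels: DoseLevelSet) -> DoseLevelSet:
    """Remove single-slice (or empty) levels, merging voxels downward.

    Every level failing :func:`check_substructure_validity` is recorded in
    ``dropped_levels`` (1-based). Its voxels join the nearest lower surviving
    level; when no lower level survives they revert to the base-dose GTV
    (they are removed from the level partition entirely). Validity is judged
    on the original masks, before any merging.
    """
    validity = [check_substructure_validity(m) for m in levels.level_masks]
    dropped = [k + 1 for k, v in enumerate(validity) if not v.valid]
    if not dropped:
        return levels

    new_members = [m.member.copy() for m in levels.level_masks]
    for k, v in enumerate(validity):
        if v.valid:
            continue
        target = next((j for j in range(k - 1, -1, -1) if validity[j].valid), None)
        if target is not None:
            new_members[target] |= new_members[k]
        new_members[k] = np.zeros(levels.grid.shape, dtype=bool)

    masks = [
        ROIMask(grid=levels.grid, member=mem, label=f"DP{k + 1}")
        for k, mem in enumerate(new_members)
    ]
    return replace(
        levels,
        level_masks=masks,
        dropped_levels=sorted(set(levels.dropped_levels) | set(dropped)),
    )


def level_volume_table(levels: DoseLevelSet) -> pd.DataFrame:
    """Per-level volumes in ccm, one row per dose level (DP1..DPn)."""
    return pd.DataFrame(
        {
            "level": [f"DP{k + 1}" for k in range(levels.n_levels)],
            "iso_pct": np.round(levels.iso_pct, 4),
            "volume_ccm": [round(m.volume_ccm, 1) for m in levels.level_masks],
            "dropped": [k + 1 in levels.dropped_levels for k in range(levels.n_levels)],
        }
    )
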