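"""Comparison of two dose-painting plans over a common GTV.

Three complementary views:

* a 2D joint histogram of voxelwise doses (plan A vs plan B);
* a quality volume histogram (QVH) of the voxelwise dose ratio A/B, with the
  quality-index (QI) fraction of voxels whose ratio falls inside an
  acceptance band (default [0.95, 1.05]);
* Dice overlap of the two plans' dose-level regions, per level, either on
  the per-level bins or on cumulative super-threshold regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import DoseMap, ROIMask, assert_same_grid
from .segmentation import DoseLevelSet

__all__ = [
    "JointDoseHistogram",
    "QVHResult",
    "DiceResult",
    "PlanComparison",
    "joint_dose_histogram",
    "qvh",
    "dice_per_level",
    "compare_plans",
]

#: Ratio grid for the QVH curve: 0 to 2 in steps of 0.001.
QVH_RATIO_GRID = np.round(np.arange(0, 2001) * 0.001, 3)


@dataclass
class JointDoseHistogram:
    """2D histogram of paired voxel doses; counts sum to the GTV voxel count."""

    bin_edges_gy: np.ndarray
    counts: np.ndarray
    n_voxels: int

    def to_dict(self) -> dict:
        return {
            "edges": [float(e) for e in self.bin_edges_gy],
            "counts": self.counts.astype(int).tolist(),
            "n_voxels": self.n_voxels,
        }


@dataclass
class QVHResult:
    """Voxelwise dose-ratio distribution between two plans.

    ``curve`` pairs each ratio threshold x with the fraction of GTV voxels
    whose ratio is >= x (DVH-style, non-increasing, starting at 1).
    """

    ratios: np.ndarray
    curve_x: np.ndarray
    curve_fraction: np.ndarray
    qi_fraction: float
    band: tuple[float, float] = (0.95, 1.05)

    def to_dict(self, curve_stride: int = 10) -> dict:
        return {
            "qi_fraction": self.qi_fraction,
            "band": list(self.band),
            "qvh_curve": [
                [float(x), float(f)]
                for x, f in zip(
                    self.curve_x[::curve_stride], self.curve_fraction[::curve_stride]
                )
            ],
        }


@dataclass
class DiceResult:
    """Per-level Dice coefficients; ``None`` marks levels empty in both plans."""

    per_level: list[tuple[int, Optional[float]]]
    mode: str = "bin"

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "dice": [{"level": k, "value": v} for k, v in self.per_level],
        }


@dataclass
class PlanComparison:
    """Bundle of all pairwise analyses plus summary scalars."""

    histogram: JointDoseHistogram
    qvh: QVHResult
    dice: DiceResult
    qi_fraction: float
    mean_dose_a_gy: float
    mean_dose_b_gy: float
    level_volumes_a_ccm: list[float] = field(default_factory=list)
    level_volumes_b_ccm: list[float] = field(default_factory=list)
    case_id: str = ""

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "qi_fraction": self.qi_fraction,
            "band": list(self.qvh.band),
            "mean_dose_a_gy": self.mean_dose_a_gy,
            "mean_dose_b_gy": self.mean_dose_b_gy,
            "level_volumes_a_ccm": self.level_volumes_a_ccm,
            "level_volumes_b_ccm": self.level_volumes_b_ccm,
            **self.dice.to_dict(),
            "histogram": self.histogram.to_dict(),
            **self.qvh.to_dict(),
        }


def joint_dose_histogram(
    map_a: DoseMap,
    map_b: DoseMap,
    gtv: ROIMask,
    bin_width_gy: float = 0.5,
) -> JointDoseHistogram:
    """Joint (A, B) dose histogram over the GTV, shared edges on both axes.

    Edges run from one bin below the lowest dose present (or the base dose,
    if known) to one bin above the highest, in steps of ``bin_width_gy``;
    bins are half-open with the top bin closed, and every GTV voxel is
    counted exactly once.
    """
    if bin_width_gy <= 0:
        raise ValueError(f"bin_width_gy must be > 0, got {bin_width_gy}")
    assert_same_grid(map_a, map_b)
    assert_same_grid(map_a, gtv)
    if gtv.voxel_count == 0:
        raise ValueError("GTV mask is empty")
    a = map_a.dose_gy[gtv.member]
    b = map_b.dose_gy[gtv.member]
    lows = [a.min(), b.min()]
    highs = [a.max(), b.max()]
    for m in (map_a, map_b):
        if m.params is not None:
            lows.append(m.params.base_dose_gy)
    lo = min(lows) - bin_width_gy
    hi = max(highs) + bin_width_gy
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width_gy)))
    edges = lo + bin_width_gy * np.arange(n_bins + 1)
    counts, _, _ = np.histogram2d(a, b, bins=[edges, edges])
    return JointDoseHistogram(
        bin_edges_gy=edges, counts=counts.astype(np.int64), n_voxels=int(a.size)
    )


def qvh(
    map_a: DoseMap,
    map_b: DoseMap,
    gtv: ROIMask,
    band: tuple[float, float] = (0.95, 1.05),
) -> QVHResult:
    """Quality volume histogram of the voxelwise ratio dose_A / dose_B.

    The QI fraction is the fraction of GTV voxels whose ratio lies in the
    closed ``band``; 1.0 means the covering plan (numerator) matches the
    reference plan (denominator) everywhere to within the band.
    """
    assert_same_grid(map_a, map_b)
    assert_same_grid(map_a, gtv)
    if gtv.voxel_count == 0:
        raise ValueError("GTV mask is empty")
    lo, hi = band
    if not lo < hi:
        raise ValueError(f"band must be ascending, got {band}")
    a = map_a.dose_gy[gtv.member]
    b = map_b.dose_gy[gtv.member]
    n_zero = int(np.count_nonzero(b == 0))
    if n_zero:
        raise ValueError(
            f"{n_zero} GTV voxel(s) with zero dose in the reference plan; "
            "expected a prescription map covering the GTV"
        )
    ratios = a / b
    sorted_r = np.sort(ratios)
    # fraction of voxels with ratio >= x, evaluated on the fixed grid
    frac = 1.0 - np.searchsorted(sorted_r, QVH_RATIO_GRID, side="left") / ratios.size
    qi = float(np.count_nonzero((ratios >= lo) & (ratios <= hi)) / ratios.size)
    return QVHResult(
        ratios=ratios,
        curve_x=QVH_RATIO_GRID.copy(),
        curve_fraction=frac,
        qi_fraction=qi,
        band=(float(lo), float(hi)),
    )


def _dice(a: np.ndarray, b: np.ndarray) -> Optional[float]:
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return None
    return 2.0 * int(np.count_nonzero(a & b)) / (na + nb)


def dice_per_level(
    levels_a: DoseLevelSet, levels_b: DoseLevelSet, mode: str = "bin"
) -> DiceResult:
    """Dice overlap of the two plans' level regions, per dose level.

    ``bin`` mode compares the per-level masks; ``cumulative`` mode compares
    the super-threshold unions of levels >= k. Levels empty in both plans
    yield ``None`` (an undefined 0/0, not agreement).
    """
    if mode not in ("bin", "cumulative"):
        raise ValueError(f"mode must be 'bin' or 'cumulative', got {mode!r}")
    if levels_a.n_levels != levels_b.n_levels:
        raise ValueError(
            f"n_levels mismatch: {levels_a.n_levels} vs {levels_b.n_levels}"
        )
    assert_same_grid(levels_a.grid, levels_b.grid)
    out: list[tuple[int, Optional[float]]] = []
    for k in range(levels_a.n_levels):
        if mode == "bin":
            ma = levels_a.level_masks[k].member
            mb = levels_b.level_masks[k].member
        else:
            ma = np.any([m.member for m in levels_a.level_masks[k:]], axis=0)
            mb = np.any([m.member for m in levels_b.level_masks[k:]], axis=0)
        out.append((k + 1, _dice(ma, mb)))
    return DiceResult(per_level=out, mode=mode)


def compare_plans(
    map_a: DoseMap,
    levels_a: DoseLevelSet,
    map_b: DoseMap,
    levels_b: DoseLevelSet,
    gtv: ROIMask,
    band: tuple[float, float] = (0.95, 1.05),
    dice_mode: str = "bin",
    bin_width_gy: float = 0.5,
    case_id: str = "",
) -> PlanComparison:
    """Run all three pairwise analyses and bundle them into one report."""
    hist = joint_dose_histogram(map_a, map_b, gtv, bin_width_gy=bin_width_gy)
    q = qvh(map_a, map_b, gtv, band=band)
    d = dice_per_level(levels_a, levels_b, mode=dice_mode)
    return PlanComparison(
        histogram=hist,
        qvh=q,
        dice=d,
        qi_fraction=q.qi_fraction,
        mean_dose_a_gy=map_a.mean_in(gtv),
        mean_dose_b_gy=map_b.mean_in(gtv),
        level_volumes_a_ccm=[m.volume_ccm for m in levels_a.level_masks],
        level_volumes_b_ccm=[m.volume_ccm for m in levels_b.level_masks],
        case_id=case_id,
    )
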