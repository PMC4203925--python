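"""Dose prescription: linear escalation from PET uptake to prescribed dose.

Each dose level receives a fraction of the base dose determined by its
bin-midpoint uptake (SUV_iso, percent of max) relative to the cut-off
(SUV_c)::

    dose(%) = 100 + (SUV_iso - SUV_c) / (100 - SUV_c) * (max_pct - 100)

so uptake at the cut-off maps to 100% of the base dose and uptake at
SUV_max to ``max_pct`` (default 150%). With ``n`` equal-width bins the level
percentages are independent of the cut-off: the k-th midpoint satisfies
``(iso - c)/(100 - c) = (2k - 1)/(2n)``, giving 105/115/125/135/145% of base
for five levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import DoseMap, ROIMask, assert_same_grid
from .segmentation import DoseLevelSet

__all__ = [
    "PrescriptionParams",
    "level_dose",
    "all_level_doses",
    "build_prescription_map",
    "emulate_delivery",
    "level_dose_table",
]


@dataclass(frozen=True)
class PrescriptionParams:
    """Prescription settings.

    base_dose_gy
        Dose at 100%, delivered to the whole GTV. Default 45 Gy
        (4.5 Gy x 10 fractions, a standard pre-operative sarcoma protocol).
    max_escalation_pct
        Dose (percent of base) at 100% of max uptake. Default 150.
    n_levels
        Number of discrete escalation levels. Default 5.
    delivery_sigma_mm
        Gaussian width of the optional deliverability surrogate; 0 disables.
    """

    base_dose_gy: float = 45.0
    max_escalation_pct: float = 150.0
    n_levels: int = 5
    delivery_sigma_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.base_dose_gy <= 0:
            raise ValueError(f"base_dose_gy must be > 0, got {self.base_dose_gy}")
        if self.max_escalation_pct <= 100:
            raise ValueError(
                f"max_escalation_pct must be > 100, got {self.max_escalation_pct}"
            )
        if self.n_levels < 1:
            raise ValueError(f"n_levels must be >= 1, got {self.n_levels}")
        if self.delivery_sigma_mm < 0:
            raise ValueError(f"delivery_sigma_mm must be >= 0, got {self.delivery_sigma_mm}")


def level_dose(iso_pct: float, cutoff_pct: float, params: PrescriptionParams) -> float:
    """Prescribed dose (Gy) for a level with midpoint uptake ``iso_pct``."""
    if cutoff_pct >= 100:
        raise ValueError(f"cutoff_pct must be < 100, got {cutoff_pct}")
    if not (cutoff_pct <= iso_pct <= 100):
        raise ValueError(
            f"iso_pct {iso_pct} outside [cutoff_pct, 100] = [{cutoff_pct}, 100]"
        )
    escalation = (iso_pct - cutoff_pct) / (100.0 - cutoff_pct)
    pct = 100.0 + escalation * (params.max_escalation_pct - 100.0)
    return params.base_dose_gy * pct / 100.0


def all_level_doses(levels: DoseLevelSet, params: PrescriptionParams) -> np.ndarray:
    """Per-level prescribed doses (Gy), strictly increasing DP1..DPn."""
    return np.array(
        [level_dose(float(i), levels.cutoff_pct, params) for i in levels.iso_pct]
    )


def build_prescription_map(
    gtv: ROIMask, levels: DoseLevelSet, params: PrescriptionParams
) -> DoseMap:
    """Paint the voxelwise prescription over the GTV.

    GTV voxels in level k get that level's dose; GTV voxels below the cut-off
    (including any reverted from dropped levels) get the base dose; voxels
    outside the GTV get 0.
    """
    doses = all_level_doses(levels, params)
    dose = np.zeros(gtv.grid.shape)
    dose[gtv.member] = params.base_dose_gy
    for k, mask in enumerate(levels.level_masks):
        assert_same_grid(gtv, mask)
        dose[mask.member] = doses[k]
    return DoseMap(
        grid=gtv.grid, dose_gy=dose, params=params, level_doses_gy=tuple(doses)
    )


def emulate_delivery(dose_map: DoseMap, sigma_mm: float) -> DoseMap:
    """Gaussian-smooth a prescription map as a deliverability surrogate.

    A deliverable dose distribution cannot hold the sharp steps of the
    prescription; this stand-in blurs the full field with an isotropic
    physical width ``sigma_mm`` (converted to voxels via the grid spacing).
    It is an explicit surrogate for plan optimization and dose calculation,
    which are out of scope. ``sigma_mm == 0`` returns the input unchanged.
    """
    if sigma_mm < 0:
        raise ValueError(f"sigma_mm must be >= 0, got {sigma_mm}")
    if sigma_mm == 0:
        return dose_map
    sigma_vox = [sigma_mm / s for s in dose_map.grid.spacing]
    # edge replication keeps constant fields exactly constant; for a
    # prescription field (zero outside the GTV, GTV away from the grid edge)
    # it coincides with zero-padded convolution
    smoothed = gaussian_filter(dose_map.dose_gy, sigma=sigma_vox, mode="nearest")
    return DoseMap(
        grid=dose_map.grid,
        dose_gy=smoothed,
        params=dose_map.params,
        level_doses_gy=dose_map.level_doses_gy,
    )


def level_dose_table(levels: DoseLevelSet, params: PrescriptionParams) -> pd.DataFrame:
    """Per-level table: level, iso_pct, dose (Gy, 0.1 precision), volume (ccm)."""
    doses = all_level_doses(levels, params)
    return pd.DataFrame(
        {
            "level": [f"DP{k + 1}" for k in range(levels.n_levels)],
            "iso_pct": np.round(levels.iso_pct, 4),
            "dose_gy": np.round(doses, 1),
            "volume_ccm": [round(m.volume_ccm, 1) for m in levels.level_masks],
        }
    )
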