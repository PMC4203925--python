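"""Synthetic co-registered dual-tracer PET phantoms.

Each phantom holds two SUV volumes on one grid — tracer A (an FDG-like
glycolysis tracer) and tracer B (a Cu-ATSM-like hypoxia tracer) — plus an
ellipsoidal GTV and a muscle reference slab. Intratumoral heterogeneity is
modelled as a smooth Gaussian random field: white noise filtered with a
Gaussian of physical width ``smoothness_mm`` and standardized. The two
tracers share a common latent field so their voxelwise correlation is
controllable::

    Z_a = sqrt(|rho|) * S + sqrt(1 - |rho|) * L_a
    Z_b = sign(rho) * sqrt(|rho|) * S + sqrt(1 - |rho|) * L_b

with S, L_a, L_b independent standardized fields, giving population
correlation exactly ``rho``. Inside the GTV the latent field passes through
a softplus (monotone, strictly positive) and is rescaled linearly so SUV
runs from the muscle background level up to exactly ``suv_max``; outside the
GTV the volume sits at the constant background, with 5% CV noise on the
muscle slab so tumor-to-muscle cut-offs are well defined but nontrivial.

Default intensity ranges follow the tumor-characteristics table of the
five-dog cohort the phantom emulates (mean GTV 63.3 ccm, FDG SUV_max 12.5,
Cu-ATSM 3 h SUV_max 2.8). The GTV is an ellipsoid with axis ratio
1 : 1.2 : 0.8 rather than a sphere, so a high cut-off really does produce
single-slice top levels (the degeneracy seen clinically).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import ImageGrid, ROIMask, SUVVolume

__all__ = [
    "PhantomParams",
    "PhantomCase",
    "generate_phantom",
    "table1_fixture",
    "make_correlation_sweep",
    "inter_tracer_correlation",
]

#: GTV ellipsoid semi-axis ratio (x, y, z relative to the base radius).
AXIS_RATIO = (1.0, 1.2, 0.8)

#: Muscle slab thickness in voxels along the first axis.
MUSCLE_SLAB_VOX = 3


@dataclass(frozen=True)
class PhantomParams:
    """Phantom generation settings; defaults emulate the cohort averages."""

    grid: ImageGrid = field(
        default_factory=lambda: ImageGrid(shape=(48, 48, 48), spacing=(2.0, 2.0, 2.0))
    )
    gtv_volume_ccm: float = 63.3
    correlation_rho: float = 0.5
    smoothness_mm: float = 4.0
    suv_max_a: float = 12.5
    suv_max_b: float = 2.8
    background_suv: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gtv_volume_ccm <= 0:
            raise ValueError(f"gtv_volume_ccm must be > 0, got {self.gtv_volume_ccm}")
        if not -1 <= self.correlation_rho <= 1:
            raise ValueError(f"correlation_rho must be in [-1, 1], got {self.correlation_rho}")
        if self.smoothness_mm <= 0:
            raise ValueError(f"smoothness_mm must be > 0, got {self.smoothness_mm}")
        if self.background_suv <= 0:
            raise ValueError(f"background_suv must be > 0, got {self.background_suv}")
        for name in ("suv_max_a", "suv_max_b"):
            if getattr(self, name) <= self.background_suv:
                raise ValueError(f"{name} must exceed background_suv")


@dataclass
class PhantomCase:
    """A generated dual-tracer case; latent fields kept for diagnostics."""

    tracer_a: SUVVolume
    tracer_b: SUVVolume
    gtv: ROIMask
    muscle: ROIMask
    params: PhantomParams
    latent_a: np.ndarray | None = None
    latent_b: np.ndarray | None = None


def _ellipsoid_mask(grid: ImageGrid, volume_ccm: float) -> np.ndarray:
    """Centered ellipsoid of the requested volume (axis ratio AXIS_RATIO)."""
    rx, ry, rz = AXIS_RATIO
    # (4/3) pi (rx ry rz) r^3 = volume
    base_r = (volume_ccm * 1000.0 * 3.0 / (4.0 * np.pi * rx * ry * rz)) ** (1.0 / 3.0)
    semi = np.array([rx, ry, rz]) * base_r
    extent = np.array(grid.extent_mm())
    center = extent / 2.0
    if np.any(semi >= center):
        raise ValueError(
            f"GTV larger than grid: semi-axes {np.round(semi, 1)} mm do not fit "
            f"inside half-extent {np.round(center, 1)} mm"
        )
    coords = [
        (np.arange(n) + 0.5) * s for n, s in zip(grid.shape, grid.spacing)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    r2 = (
        ((xx - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((zz - center[2]) / semi[2]) ** 2
    )
    return r2 <= 1.0


def _smooth_field(rng: np.random.Generator, grid: ImageGrid, smoothness_mm: float) -> np.ndarray:
    """Standardized Gaussian random field with correlation length smoothness_mm."""
    sigma_vox = [smoothness_mm / s for s in grid.spacing]
    f = gaussian_filter(rng.standard_normal(grid.shape), sigma=sigma_vox)
    return (f - f.mean()) / f.std()


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def generate_phantom(params: PhantomParams) -> PhantomCase:
    """Generate one dual-tracer phantom case, reproducible from ``params.seed``."""
    grid = params.grid
    rng = np.random.default_rng(params.seed)

    gtv_member = _ellipsoid_mask(grid, params.gtv_volume_ccm)
    muscle_member = np.zeros(grid.shape, dtype=bool)
    muscle_member[:MUSCLE_SLAB_VOX, :, :] = True
    if np.any(muscle_member & gtv_member):
        raise ValueError("GTV larger than grid: it overlaps the muscle reference slab")

    shared = _smooth_field(rng, grid, params.smoothness_mm)
    own_a = _smooth_field(rng, grid, params.smoothness_mm)
    own_b = _smooth_field(rng, grid, params.smoothness_mm)
    rho = params.correlation_rho
    w_shared = np.sqrt(abs(rho))
    w_own = np.sqrt(1.0 - abs(rho))
    z_a = w_shared * shared + w_own * own_a
    z_b = (-1.0 if rho < 0 else 1.0) * w_shared * shared + w_own * own_b

    # one muscle-noise draw shared by both tracers (same tissue, same scan grid)
    muscle_noise = rng.standard_normal(int(muscle_member.sum()))

    volumes = []
    for z, suv_max in ((z_a, params.suv_max_a), (z_b, params.suv_max_b)):
        values = np.full(grid.shape, params.background_suv)
        t = _softplus(z[gtv_member])
        span = t.max() - t.min()
        if span > 0:
            scaled = (t - t.min()) / span
        else:
            scaled = np.ones_like(t)
        values[gtv_member] = params.background_suv + scaled * (
            suv_max - params.background_suv
        )
        values[muscle_member] = np.clip(
            params.background_suv * (1.0 + 0.05 * muscle_noise), 0.0, None
        )
        volumes.append(SUVVolume(grid=grid, values=values))

    return PhantomCase(
        tracer_a=volumes[0],
        tracer_b=volumes[1],
        gtv=ROIMask(grid=grid, member=gtv_member, label="GTV"),
        muscle=ROIMask(grid=grid, member=muscle_member, label="muscle"),
        params=params,
        latent_a=z_a,
        latent_b=z_b,
    )


def inter_tracer_correlation(case: PhantomCase, latent: bool = True) -> float:
    """Empirical within-GTV Pearson correlation of the two tracer fields.

    ``latent=True`` correlates the Gaussian latent fields (the quantity the
    ``correlation_rho`` parameter controls); ``latent=False`` the SUV fields.
    """
    m = case.gtv.member
    if latent and case.latent_a is not None:
        a, b = case.latent_a[m], case.latent_b[m]
    else:
        a, b = case.tracer_a.values[m], case.tracer_b.values[m]
    return float(np.corrcoef(a, b)[0, 1])


def table1_fixture() -> pd.DataFrame:
    """The five-case cohort summary table, plus an unweighted ``Avg.`` row.

    Columns: dog, tumor_type, localization, gtv_ccm, fdg_subvol_ccm,
    cu3_subvol_ccm, cu24_subvol_ccm, suv_max_fdg, suv_max_cu3. Numeric
    averages are rounded to one decimal, matching the published layout.
    """
    with resources.files("dosepaint.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    num_cols = [c for c in df.columns if c not in ("dog", "tumor_type", "localization")]
    avg = {c: round(float(df[c].mean()), 1) for c in num_cols}
    avg.update({"dog": "Avg.", "tumor_type": "", "localization": ""})
    return pd.concat([df.astype({"dog": str}), pd.DataFrame([avg])], ignore_index=True)


def make_correlation_sweep(
    base: PhantomParams, rhos: Sequence[float]
) -> list[PhantomCase]:
    """One phantom per rho, everything else (including the seed) held fixed."""
    return [generate_phantom(replace(base, correlation_rho=float(r))) for r in rhos]
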