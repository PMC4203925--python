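"""End-to-end orchestration: inputs -> cut-offs -> levels -> prescriptions -> comparisons.

A run is described by a single config (YAML/JSON mapping). Defaults reproduce
the reference analysis settings: three plans per case — an FDG-like plan on
tracer A (cut-off 40% of SUV_max), an early hypoxia-tracer plan on tracer B
(absolute SUV 1.4) and a late one on tracer B (tumor-to-muscle ratio 2.0) —
a 45 Gy base dose escalated over five levels to at most 150%, and pairwise
comparisons with a [0.95, 1.05] QI band.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparison import PlanComparison, compare_plans
from .core import ImageGrid
from .io import read_mask, read_volume, write_json, write_label_volume, write_volume
from .phantom import PhantomParams, generate_phantom
from .prescription import (
    PrescriptionParams,
    build_prescription_map,
    emulate_delivery,
    level_dose_table,
)
from .segmentation import (
    DoseLevelSet,
    ThresholdSpec,
    build_dose_levels,
    compute_cutoff,
    drop_degenerate_levels,
)

__all__ = [
    "ConfigError",
    "PlanSpec",
    "RunConfig",
    "CaseReport",
    "validate_config",
    "run_case",
    "summarize_cases",
]

logger = logging.getLogger("dosepaint")

SCHEMA_VERSION = 1

DEFAULT_PLANS = (
    {"name": "fdg", "tracer": "a", "method": "percent_max", "value": 40.0},
    {"name": "cu3", "tracer": "b", "method": "absolute_suv", "value": 1.4},
    {"name": "cu24", "tracer": "b", "method": "tumor_to_muscle", "value": 2.0},
)


class ConfigError(ValueError):
    """Invalid run configuration; the message lists every violation."""


@dataclass(frozen=True)
class PlanSpec:
    """One dose-painting plan: a tracer volume plus its threshold rule."""

    name: str
    tracer: str  # "a" or "b"
    threshold: ThresholdSpec


@dataclass
class RunConfig:
    """Validated end-to-end run configuration."""

    source: str  # "phantom" or "files"
    case_id: str
    seed: int
    phantom: Optional[PhantomParams]
    paths: dict[str, str]
    plans: list[PlanSpec]
    prescription: PrescriptionParams
    band: tuple[float, float] = (0.95, 1.05)
    dice_mode: str = "bin"
    bin_width_gy: float = 0.5
    raw: dict = field(default_factory=dict, repr=False)

    def canonical_json(self) -> str:
        return json.dumps(self.raw, sort_keys=True, separators=(",", ":"))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def _phantom_params(section: dict, seed: int, errors: list[str]) -> Optional[PhantomParams]:
    kwargs: dict[str, Any] = {"seed": seed}
    grid_sec = section.pop("grid", None)
    known = {
        "gtv_volume_ccm",
        "correlation_rho",
        "smoothness_mm",
        "suv_max_a",
        "suv_max_b",
        "background_suv",
        "seed",
    }
    for key, val in section.items():
        if key not in known:
            errors.append(f"phantom: unknown key {key!r}")
        else:
            kwargs[key] = val
    if grid_sec is not None:
        try:
            kwargs["grid"] = ImageGrid(
                shape=tuple(grid_sec.get("shape", (48, 48, 48))),
                spacing=tuple(grid_sec.get("spacing", (2.0, 2.0, 2.0))),
                origin=tuple(grid_sec.get("origin", (0.0, 0.0, 0.0))),
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"phantom.grid: {exc}")
    try:
        return PhantomParams(**kwargs)
    except (ValueError, TypeError) as exc:
        errors.append(f"phantom: {exc}")
        return None


def validate_config(raw: str | dict | None) -> RunConfig:
    """Parse and validate a config mapping (or YAML/JSON text).

    Unknown keys and out-of-range values are collected and reported together
    in a single :class:`ConfigError`. Missing sections fall back to the
    reference defaults.
    """
    if raw is None:
        raw = {}
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    data = dict(raw)
    errors: list[str] = []

    top_known = {
        "schema_version",
        "source",
        "case_id",
        "seed",
        "phantom",
        "paths",
        "plans",
        "prescription",
        "comparison",
    }
    for key in data:
        if key not in top_known:
            errors.append(f"unknown key {key!r}")

    schema = data.get("schema_version", SCHEMA_VERSION)
    if schema != SCHEMA_VERSION:
        errors.append(f"unsupported schema_version {schema!r} (expected {SCHEMA_VERSION})")

    source = data.get("source", "phantom")
    if source not in ("phantom", "files"):
        errors.append(f"source must be 'phantom' or 'files', got {source!r}")

    seed = data.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed must be an integer, got {seed!r}")
        seed = 0
    case_id = str(data.get("case_id", f"{source}-{seed}"))

    phantom = None
    paths: dict[str, str] = {}
    if source == "phantom":
        phantom = _phantom_params(dict(data.get("phantom", {}) or {}), seed, errors)
    elif source == "files":
        paths = dict(data.get("paths", {}) or {})
        for key in ("volume_a", "volume_b", "gtv"):
            if key not in paths:
                errors.append(f"paths: missing required key {key!r}")
            elif not Path(paths[key]).exists():
                errors.append(f"paths.{key}: file not found: {paths[key]}")
        if "muscle" in paths and not Path(paths["muscle"]).exists():
            errors.append(f"paths.muscle: file not found: {paths['muscle']}")

    plan_specs: list[PlanSpec] = []
    for i, p in enumerate(data.get("plans", [dict(d) for d in DEFAULT_PLANS])):
        p = dict(p)
        name = str(p.get("name", f"plan{i + 1}"))
        tracer = p.get("tracer", "a")
        if tracer not in ("a", "b"):
            errors.append(f"plans[{i}].tracer must be 'a' or 'b', got {tracer!r}")
            continue
        try:
            thr = ThresholdSpec(method=p.get("method", "percent_max"), value=p.get("value", 40.0))
        except ValueError as exc:
            errors.append(f"plans[{i}]: {exc}")
            continue
        plan_specs.append(PlanSpec(name=name, tracer=tracer, threshold=thr))
    if not plan_specs and not errors:
        errors.append("plans: at least one plan is required")

    presc_sec = dict(data.get("prescription", {}) or {})
    try:
        prescription = PrescriptionParams(**presc_sec)
    except (ValueError, TypeError) as exc:
        errors.append(f"prescription: {exc}")
        prescription = PrescriptionParams()

    comp = dict(data.get("comparison", {}) or {})
    band = tuple(comp.get("band", (0.95, 1.05)))
    if len(band) != 2 or not band[0] < band[1]:
        errors.append(f"comparison.band not ascending: {band}")
        band = (0.95, 1.05)
    dice_mode = comp.get("dice_mode", "bin")
    if dice_mode not in ("bin", "cumulative"):
        errors.append(f"comparison.dice_mode must be 'bin' or 'cumulative', got {dice_mode!r}")
    bin_width = float(comp.get("bin_width_gy", 0.5))
    if bin_width <= 0:
        errors.append(f"comparison.bin_width_gy must be > 0, got {bin_width}")

    if errors:
        raise ConfigError("invalid config:\n  - " + "\n  - ".join(errors))

    return RunConfig(
        source=source,
        case_id=case_id,
        seed=seed,
        phantom=phantom,
        paths=paths,
        plans=plan_specs,
        prescription=prescription,
        band=(float(band[0]), float(band[1])),
        dice_mode=dice_mode,
        bin_width_gy=bin_width,
        raw=data,
    )


@dataclass
class CaseReport:
    """Everything computed for one case, regenerable from its provenance block."""

    case_id: str
    plans: dict[str, dict]
    comparisons: dict[str, PlanComparison]
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "plans": self.plans,
            "comparisons": {k: v.to_dict() for k, v in self.comparisons.items()},
            "provenance": self.provenance,
        }

    def qi_fractions(self) -> dict[str, float]:
        return {k: v.qi_fraction for k, v in self.comparisons.items()}


def _load_inputs(config: RunConfig):
    if config.source == "phantom":
        case = generate_phantom(config.phantom)
        volumes = {"a": case.tracer_a, "b": case.tracer_b}
        return volumes, case.gtv, case.muscle
    volumes = {
        "a": read_volume(config.paths["volume_a"]),
        "b": read_volume(config.paths["volume_b"]),
    }
    gtv = read_mask(config.paths["gtv"], label="GTV")
    muscle = (
        read_mask(config.paths["muscle"], label="muscle")
        if "muscle" in config.paths
        else None
    )
    return volumes, gtv, muscle


def run_case(config: RunConfig, outdir: Optional[Path | str] = None) -> CaseReport:
    """Run segmentation, prescription and all pairwise comparisons for one case.

    When ``outdir`` is given, writes per-plan NIfTI dose maps and level-label
    volumes, CSV tables (level doses/volumes, QI fractions, Dice per level)
    and the full JSON report there. Inputs are never modified.
    """
    volumes, gtv, muscle = _load_inputs(config)

    stage = "segmentation"
    try:
        plan_results: dict[str, dict] = {}
        levels_by_plan: dict[str, DoseLevelSet] = {}
        maps_by_plan = {}
        for plan in config.plans:
            vol = volumes[plan.tracer]
            cutoff = compute_cutoff(vol, gtv, plan.threshold, muscle=muscle)
            levels = build_dose_levels(
                vol, gtv, cutoff, n_levels=config.prescription.n_levels
            )
            levels = drop_degenerate_levels(levels)
            for k in levels.dropped_levels:
                logger.info(
                    "case %s plan %s: dropped degenerate level DP%d (<=1 axial slice)",
                    config.case_id,
                    plan.name,
                    k,
                )
            stage = "prescription"
            dmap = build_prescription_map(gtv, levels, config.prescription)
            if config.prescription.delivery_sigma_mm > 0:
                dmap = emulate_delivery(dmap, config.prescription.delivery_sigma_mm)
            levels_by_plan[plan.name] = levels
            maps_by_plan[plan.name] = dmap
            plan_results[plan.name] = {
                "tracer": plan.tracer,
                "threshold": {"method": plan.threshold.method, "value": plan.threshold.value},
                **levels.summary(),
                "level_doses_gy": [float(d) for d in dmap.level_doses_gy],
                "mean_gtv_dose_gy": dmap.mean_in(gtv),
            }
            stage = "segmentation"

        stage = "comparison"
        comparisons: dict[str, PlanComparison] = {}
        for pa, pb in itertools.combinations([p.name for p in config.plans], 2):
            pair = f"{pa}_vs_{pb}"
            comparisons[pair] = compare_plans(
                maps_by_plan[pa],
                levels_by_plan[pa],
                maps_by_plan[pb],
                levels_by_plan[pb],
                gtv,
                band=config.band,
                dice_mode=config.dice_mode,
                bin_width_gy=config.bin_width_gy,
                case_id=config.case_id,
            )
    except Exception as exc:
        raise RuntimeError(f"case {config.case_id}: {stage} stage failed: {exc}") from exc

    report = CaseReport(
        case_id=config.case_id,
        plans=plan_results,
        comparisons=comparisons,
        provenance={
            "schema_version": SCHEMA_VERSION,
            "config": config.raw,
            "config_hash": config.config_hash,
            "seed": config.seed,
            "software_version": __version__,
        },
    )
    if outdir is not None:
        _write_outputs(report, config, volumes, gtv, levels_by_plan, maps_by_plan, Path(outdir))
    return report


def _write_outputs(report, config, volumes, gtv, levels_by_plan, maps_by_plan, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(gtv, outdir / "gtv.nii.gz")
    for name, dmap in maps_by_plan.items():
        write_volume(dmap, outdir / f"dose_{name}.nii.gz")
    for name, levels in levels_by_plan.items():
        write_label_volume(levels, outdir / f"levels_{name}.nii.gz")
        level_dose_table(levels, config.prescription).to_csv(
            outdir / f"levels_{name}.csv", index=False
        )
    qi = pd.DataFrame(
        [{"case_id": report.case_id, **report.qi_fractions()}]
    )
    qi.to_csv(outdir / "qi_fractions.csv", index=False)
    dice_rows = []
    for pair, comp in report.comparisons.items():
        for level, value in comp.dice.per_level:
            dice_rows.append(
                {"pair": pair, "level": f"DP{level}",
                 "dice": None if value is None else round(value, 4)}
            )
    pd.DataFrame(dice_rows).to_csv(outdir / "dice_per_level.csv", index=False)
    write_json(report.to_dict(), outdir / "report.json")


def summarize_cases(reports: list[CaseReport]) -> dict[str, pd.DataFrame]:
    """Cohort summary: per-case QI fractions with an unweighted mean row, and
    mean per-level volumes across cases for each plan."""
    if not reports:
        raise ValueError("at least one case report is required")
    qi_rows = [{"case_id": r.case_id, **r.qi_fractions()} for r in reports]
    qi = pd.DataFrame(qi_rows)
    pair_cols = [c for c in qi.columns if c != "case_id"]
    mean_row = {"case_id": "Mean", **{c: round(float(qi[c].mean()), 2) for c in pair_cols}}
    qi_out = pd.concat(
        [qi.assign(**{c: qi[c].round(2) for c in pair_cols}), pd.DataFrame([mean_row])],
        ignore_index=True,
    )

    vol_rows = []
    plan_names = list(reports[0].plans)
    n_levels = reports[0].plans[plan_names[0]]["n_levels"]
    for k in range(n_levels):
        row: dict[str, Any] = {"level": f"DP{k + 1}"}
        for name in plan_names:
            vols = [r.plans[name]["level_volumes_ccm"][k] for r in reports]
            row[f"{name}_ccm"] = round(float(np.mean(vols)), 2)
        vol_rows.append(row)
    return {"qi_fractions": qi_out, "level_volumes": pd.DataFrame(vol_rows)}
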