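"""End-to-end study driver: mesh, solve, and score every condition.

Reproduces the comparative study design: two anatomical models, four
pressure magnitudes (2, 6, 8, 10 kPa), three stiffness levels (baseline,
-10 %, -20 %), with exposure measured against thresholds fixed from the
reference model (model1) at baseline stiffness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .anatomy import AnatomyModel, LoadCase, builtin_model, make_variants
from .exposure import exposure_report, reference_thresholds
from .field_metrics import solution_table
from .meshing import Mesh, build_mesh
from .solver import SolverSettings, SolveError, apply_load, solve

__all__ = ["ConditionResult", "solve_condition", "run_study", "headline_results", "trend_checks", "StudyResult"]


@dataclass
class ConditionResult:
    model: AnatomyModel
    pressure: float
    mesh: Mesh
    solution: object
    table: pd.DataFrame
    error: str | None = None


@dataclass
class StudyResult:
    thresholds: pd.DataFrame
    report: pd.DataFrame
    conditions: Dict[Tuple[str, float, float], ConditionResult]
    failures: List[Tuple[str, float, float, str]]


def solve_condition(
    model: AnatomyModel,
    pressure: float,
    resolution: str = "medium",
    settings: SolverSettings | None = None,
    mesh: Mesh | None = None,
    contact_mode: str = "traction_patch",
) -> ConditionResult:
    """Mesh (or reuse a mesh) and solve one (model, pressure) condition.

    ``contact_mode`` selects how the sensor load is delivered: a uniform
    follower traction over the patch ("traction_patch") or a frictionless
    rigid punch displaced until its reaction balances the applied pressure
    ("rigid_punch", closest to sensor-mediated loading).
    """
    from .solver import solve_rigid_punch

    mesh = mesh if mesh is not None else build_mesh(model, resolution)
    if contact_mode == "rigid_punch":
        sol = solve_rigid_punch(mesh, model, pressure, settings=settings)
    else:
        load = apply_load(mesh, LoadCase(pressure=pressure, contact_mode=contact_mode))
        sol = solve(mesh, model, load=load, settings=settings)
    return ConditionResult(model=model, pressure=pressure, mesh=mesh, solution=sol, table=solution_table(mesh, sol))


def run_study(
    model_ids: Sequence[str] = ("model1", "model2"),
    pressures: Sequence[float] = (2.0, 6.0, 8.0, 10.0),
    fractions: Sequence[float] = (0.1, 0.2),
    resolution: str = "medium",
    settings: SolverSettings | None = None,
    reference_model: str = "model1",
    contact_mode: str = "traction_patch",
) -> StudyResult:
    """Solve the full grid and build thresholds and the exposure report.

    The reference model at baseline stiffness must be part of the grid; its
    ROI-restricted volume-weighted 75th percentiles (per tissue, pressure
    and quantity) are the fixed thresholds for every condition.  Failed
    solves are recorded and their rows omitted rather than aborting the
    sweep.
    """
    if reference_model not in model_ids:
        raise ValueError("the reference model must be included in the study")
    conditions: Dict[Tuple[str, float, float], ConditionResult] = {}
    failures: List[Tuple[str, float, float, str]] = []
    for model_id in model_ids:
        base = builtin_model(model_id)
        variants = [base] + make_variants(base, fractions)
        mesh = build_mesh(base, resolution)  # geometry identical across stiffness variants
        for variant in variants:
            for p in pressures:
                key = (model_id, float(p), variant.stiffness_factor)
                try:
                    conditions[key] = solve_condition(
                        variant, p, settings=settings, mesh=mesh, contact_mode=contact_mode
                    )
                except SolveError as exc:
                    failures.append((*key, str(exc)))

    ref_tables = {
        p: conditions[(reference_model, float(p), 1.0)].table
        for p in pressures
        if (reference_model, float(p), 1.0) in conditions
    }
    if len(ref_tables) != len(pressures):
        missing = [p for p in pressures if p not in ref_tables]
        raise SolveError(f"reference model failed at pressure(s) {missing}; no thresholds")
    thresholds = reference_thresholds(ref_tables, provenance=reference_model)
    report = exposure_report({k: c.table for k, c in conditions.items()}, thresholds)
    return StudyResult(thresholds=thresholds, report=report, conditions=conditions, failures=failures)


def headline_results(
    resolution: str = "medium",
    contact_mode: str = "rigid_punch",
    pressure: float = 10.0,
    fractions: Tuple[float, float] = (0.1, 0.2),
) -> Dict[str, float]:
    """Recompute the study's headline comparison quantities at one pressure.

    Solves Model 1 and Model 2 at baseline plus the softened variants under
    the sensor load, derives Model-1 baseline thresholds, and returns the
    depth-profile ratios and exposure percentages used for cross-model
    comparison (plus the mesh sizes used).
    """
    from .field_metrics import layer_ratio_profile

    tables: Dict[Tuple[str, float, float], pd.DataFrame] = {}
    n_elements = {}
    for model_id in ("model1", "model2"):
        base = builtin_model(model_id)
        mesh = build_mesh(base, resolution)
        n_elements[model_id] = mesh.n_elements
        for variant in [base] + make_variants(base, fractions):
            key = (model_id, pressure, variant.stiffness_factor)
            tables[key] = solve_condition(
                variant, pressure, mesh=mesh, contact_mode=contact_mode
            ).table
    thresholds = reference_thresholds({pressure: tables[("model1", pressure, 1.0)]})
    report = exposure_report(tables, thresholds)

    def expo(model: str, s: float, tissue: str, quantity: str) -> float:
        sel = report[
            (report["model"] == model)
            & np.isclose(report["stiffness_factor"], s)
            & (report["tissue"] == tissue)
            & (report["quantity"] == quantity)
        ]
        return float(sel["exposure_volume_pct"].iloc[0])

    m1 = tables[("model1", pressure, 1.0)]
    stress_ratios = layer_ratio_profile(m1, "sigma_vm_kPa", normalize_to="adipose")
    strain_ratios = layer_ratio_profile(m1, "eps_eff", normalize_to="epidermis")
    s10, s20 = 1.0 - fractions[0], 1.0 - fractions[1]
    return {
        "stress_ratio_epidermis_to_adipose": stress_ratios["epidermis"],
        "strain_ratio_adipose_to_epidermis": strain_ratios["adipose"],
        "dermis_stress_exposure_model1": expo("model1", 1.0, "dermis", "stress"),
        "muscle_stress_exposure_model1": expo("model1", 1.0, "muscle", "stress"),
        "muscle_stress_exposure_model2": expo("model2", 1.0, "muscle", "stress"),
        "muscle_strain_exposure_model2": expo("model2", 1.0, "muscle", "strain"),
        "adipose_strain_exposure_model1": expo("model1", 1.0, "adipose", "strain"),
        "total_stress_exposure_model1_baseline": expo("model1", 1.0, "total", "stress"),
        "total_stress_exposure_model1_soft20": expo("model1", s20, "total", "stress"),
        "total_strain_exposure_model2_baseline": expo("model2", 1.0, "total", "strain"),
        "total_strain_exposure_model2_soft20": expo("model2", s20, "total", "strain"),
        "muscle_strain_exposure_model2_soft10": expo("model2", s10, "muscle", "strain"),
        "n_elements_model1": n_elements["model1"],
        "n_elements_model2": n_elements["model2"],
    }


def trend_checks(report: pd.DataFrame, high_pressure: float = 10.0, low_pressure: float = 2.0) -> Dict[str, bool]:
    """Headline ordinal trends of the study as pass/fail assertions.

    * softening_increases_exposure: total exposure strictly increases from
      baseline through -10 % to -20 % stiffness at the high pressure.
    * model2_exceeds_model1: model2 total exposure >= model1 at 8-10 kPa.
    * low_pressure_negligible: total exposure at 2 kPa is far below 10 kPa.
    """
    tot = report[(report["tissue"] == "total")]
    out: Dict[str, bool] = {}

    def total(model, p, s, quantity):
        sel = tot[
            (tot["model"] == model)
            & np.isclose(tot["pressure_kPa"], p)
            & np.isclose(tot["stiffness_factor"], s)
            & (tot["quantity"] == quantity)
        ]
        return float(sel["exposure_volume_pct"].iloc[0]) if len(sel) else np.nan

    factors = sorted(tot["stiffness_factor"].unique(), reverse=True)
    ok = True
    for model in tot["model"].unique():
        for quantity in ("stress", "strain"):
            vals = [total(model, high_pressure, s, quantity) for s in factors]
            ok &= all(b > a for a, b in zip(vals, vals[1:]))
    out["softening_increases_exposure"] = bool(ok)

    ok = True
    for p in (8.0, 10.0):
        for quantity in ("stress", "strain"):
            for s in factors:
                m1, m2 = total("model1", p, s, quantity), total("model2", p, s, quantity)
                if np.isfinite(m1) and np.isfinite(m2):
                    ok &= m2 >= m1
    out["model2_exceeds_model1"] = bool(ok)

    ok = True
    for model in tot["model"].unique():
        for quantity in ("stress", "strain"):
            lo = total(model, low_pressure, 1.0, quantity)
            hi = total(model, high_pressure, 1.0, quantity)
            if np.isfinite(lo) and np.isfinite(hi):
                ok &= lo <= 0.5 * hi
    out["low_pressure_negligible"] = bool(ok)
    return out
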