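"""Scalar effective measures and layer-wise aggregation.

von Mises (effective) stress: sigma_vm = sqrt(3/2 s:s) with s the stress
deviator.  Effective strain: eps_eff = sqrt(2/3 e:e) with e the deviatoric
logarithmic strain — normalized so an incompressible uniaxial stretch
lambda gives eps_eff = |ln lambda|, which pairs with the 3-6 % therapeutic
and > 9 % damage strain benchmarks used for interpretation.

Layer summaries are volume-weighted means (optionally peaks) over either
the region of interest or the whole layer.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .anatomy import SOFT_LAYERS

__all__ = [
    "von_mises",
    "effective_strain",
    "solution_table",
    "layer_average",
    "layer_summary",
    "layer_ratio_profile",
]


def _deviator_contraction(T: np.ndarray) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    single = T.ndim == 2
    if single:
        T = T[None]
    tr = np.trace(T, axis1=-2, axis2=-1)
    dev = T - tr[:, None, None] / 3.0 * np.eye(3)
    dd = np.einsum("...ij,...ij->...", dev, dev)
    return dd[0] if single else dd


def von_mises(sigma: np.ndarray) -> float | np.ndarray:
    """sqrt(3/2 s:s) of one (3,3) tensor or a stack (n,3,3)."""
    out = np.sqrt(1.5 * _deviator_contraction(sigma))
    return float(out) if np.ndim(out) == 0 else out


def effective_strain(eps: np.ndarray) -> float | np.ndarray:
    """sqrt(2/3 e:e) of one (3,3) strain tensor or a stack (n,3,3)."""
    out = np.sqrt(2.0 / 3.0 * _deviator_contraction(eps))
    return float(out) if np.ndim(out) == 0 else out


def solution_table(mesh, solution) -> pd.DataFrame:
    """Per-element results table (shared CSV schema) from a solved field."""
    from .io import element_table  # local import to avoid a cycle

    return element_table(
        mesh,
        sigma_vm=von_mises(solution.element_stress),
        eps_eff=effective_strain(solution.element_strain),
    )


def _select(df: pd.DataFrame, layer: str | None, roi_only: bool) -> pd.DataFrame:
    sel = df
    if layer is not None:
        sel = sel[sel["layer"] == layer]
    if roi_only:
        sel = sel[sel["roi"] == 1]
    if sel.empty:
        raise ValueError(f"empty selection (layer={layer!r}, roi_only={roi_only})")
    return sel


def layer_average(df: pd.DataFrame, layer: str, roi_only: bool = True) -> Mapping[str, float]:
    """Volume-weighted mean stress and strain of one layer."""
    sel = _select(df, layer, roi_only)
    w = sel["volume_mm3"].to_numpy()
    return {
        "sigma_vm_kPa": float(np.average(sel["sigma_vm_kPa"], weights=w)),
        "eps_eff": float(np.average(sel["eps_eff"], weights=w)),
    }


def layer_summary(df: pd.DataFrame, layers: Iterable[str] = SOFT_LAYERS, roi_only: bool = True) -> pd.DataFrame:
    """Tidy per-layer summary: volume-weighted mean and peak of both fields."""
    rows = []
    for layer in layers:
        sel = _select(df, layer, roi_only)
        w = sel["volume_mm3"].to_numpy()
        rows.append(
            {
                "layer": layer,
                "volume_mm3": float(w.sum()),
                "mean_sigma_vm_kPa": float(np.average(sel["sigma_vm_kPa"], weights=w)),
                "max_sigma_vm_kPa": float(sel["sigma_vm_kPa"].max()),
                "mean_eps_eff": float(np.average(sel["eps_eff"], weights=w)),
                "max_eps_eff": float(sel["eps_eff"].max()),
            }
        )
    return pd.DataFrame(rows)


def layer_ratio_profile(
    df: pd.DataFrame,
    quantity: str = "sigma_vm_kPa",
    normalize_to: str = "adipose",
    layers: Iterable[str] = SOFT_LAYERS,
    roi_only: bool = True,
    statistic: str = "mean",
) -> Mapping[str, float]:
    """Per-layer means (or peaks) divided by the normalizing layer's value.

    The conventional bases are adipose for stress and epidermis for strain,
    matching the X:Y:Z:W ratio format used to describe depth profiles.
    """
    values = {}
    for layer in layers:
        sel = _select(df, layer, roi_only)
        if statistic == "mean":
            values[layer] = float(np.average(sel[quantity], weights=sel["volume_mm3"]))
        elif statistic == "peak":
            values[layer] = float(sel[quantity].max())
        else:
            raise ValueError("statistic must be 'mean' or 'peak'")
    ref = values[normalize_to]
    if ref == 0:
        raise ValueError(f"normalizing layer {normalize_to!r} has zero {statistic}")
    return {layer: v / ref for layer, v in values.items()}
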