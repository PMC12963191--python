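"""Analytic benchmarks and synthetic field ensembles for verification.

Everything here is solver-independent: closed forms and scalar
root-finding only, so these results can serve as oracles for the finite
element solution, and the synthetic ensembles exercise the exposure
pipeline without running the solver at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .materials import MaterialParams

__all__ = [
    "uniaxial_strain_benchmark",
    "circular_load_halfspace_benchmark",
    "SyntheticFieldSpec",
    "generate_field",
    "two_cohort_fixture",
    "lognormal_exceedance",
]


def uniaxial_strain_benchmark(material: MaterialParams, pressure: float):
    """Confined (uniaxial-strain) compression of a Neo-Hookean solid.

    With lateral stretches fixed at 1 and axial stretch J, the axial first
    Piola-Kirchhoff stress is P(J) = mu J - mu / J + lam ln J / J, which
    also equals the axial Cauchy stress (the cross-section is unchanged).
    Solves P(J) = -pressure by bracketed root-finding.

    Returns ``(J, sigma, eps)`` with sigma the Cauchy stress tensor
    diag(sigma_lat, -p, sigma_lat) and eps the Hencky strain
    diag(0, ln J, 0), axis ordering (r, z, theta) with z the loaded axis.
    """
    mu, lam = material.mu, material.lam

    def P(J):
        return mu * J - mu / J + lam * np.log(J) / J

    if pressure == 0.0:
        J = 1.0
    else:
        lo, hi = 1e-6, 1.0
        if pressure < 0:  # tension
            lo, hi = 1.0, 1e6
        try:
            J = brentq(lambda x: P(x) + pressure, lo, hi, xtol=1e-14, rtol=1e-15)
        except ValueError as exc:
            raise ValueError(f"no bracket for pressure {pressure}") from exc
    lnJ = np.log(J)
    # lateral Cauchy stress: sigma_lat = (mu (1 - 1) + lam lnJ)/J (B_lat = 1)
    s_lat = lam * lnJ / J
    sigma = np.diag([s_lat, P(J), s_lat])
    eps = np.diag([0.0, lnJ, 0.0])
    return J, sigma, eps


def circular_load_halfspace_benchmark(E: float, nu: float, p: float, a: float) -> float:
    """Center surface settlement under uniform pressure on a circular area
    of a linear-elastic half space: w0 = 2 p a (1 - nu^2) / E."""
    if E <= 0 or a <= 0:
        raise ValueError("E and a must be positive")
    return 2.0 * p * a * (1.0 - nu * nu) / E


@dataclass(frozen=True)
class SyntheticFieldSpec:
    """Per-layer scalar-field distributions standing in for solver output.

    ``layers`` maps layer name to a distribution spec
    ``(family, params, volume_budget)`` with family one of "lognormal"
    (params: mu, sigma of log), "uniform" (lo, hi) or "gamma" (shape,
    scale); the volume budget is shared equally among that layer's
    elements.  ``n`` is the element count per layer.
    """

    layers: Dict[str, Tuple[str, Tuple[float, ...], float]]
    n: int
    seed: int
    roi_fraction: float = 1.0  # fraction of elements flagged as ROI

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        for name, (family, params, vol) in self.layers.items():
            if vol <= 0:
                raise ValueError(f"{name}: volume budget must be positive")
            if family not in ("lognormal", "uniform", "gamma"):
                raise ValueError(f"{name}: unknown family {family!r}")


def _draw(rng: np.random.Generator, family: str, params: Tuple[float, ...], n: int) -> np.ndarray:
    if family == "lognormal":
        mu, sigma = params
        return rng.lognormal(mean=mu, sigma=sigma, size=n)
    if family == "uniform":
        lo, hi = params
        if hi < lo:
            raise ValueError("uniform: hi < lo")
        return rng.uniform(lo, hi, size=n)
    shape, scale = params
    return rng.gamma(shape, scale, size=n)


def generate_field(spec: SyntheticFieldSpec, quantity: str = "strain") -> pd.DataFrame:
    """Seeded synthetic per-element table in the shared CSV schema.

    The drawn values populate one field column ("strain" -> eps_eff,
    "stress" -> sigma_vm_kPa); the other column is zero-filled.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    eid = 0
    for name in sorted(spec.layers):
        family, params, vol = spec.layers[name]
        values = _draw(rng, family, params, spec.n)
        n_roi = int(round(spec.roi_fraction * spec.n))
        roi = np.zeros(spec.n, dtype=int)
        roi[:n_roi] = 1
        frames.append(
            pd.DataFrame(
                {
                    "element_id": np.arange(eid, eid + spec.n),
                    "layer": name,
                    "r_mm": np.zeros(spec.n),
                    "z_mm": np.zeros(spec.n),
                    "volume_mm3": np.full(spec.n, vol / spec.n),
                    "roi": roi,
                    "sigma_vm_kPa": values if quantity == "stress" else np.zeros(spec.n),
                    "eps_eff": values if quantity == "strain" else np.zeros(spec.n),
                }
            )
        )
        eid += spec.n
    return pd.concat(frames, ignore_index=True)


def lognormal_exceedance(mu: float, sigma: float, threshold: float) -> float:
    """P(X > T) for X ~ lognormal(mu, sigma) — closed-form tail."""
    from scipy.stats import norm

    if threshold <= 0:
        return 1.0
    return float(norm.sf((np.log(threshold) - mu) / sigma))


def two_cohort_fixture(effect: float, seed: int, n: int = 20000, sigma: float = 0.6):
    """Paired synthetic strain-field cohorts emulating two anatomies.

    Cohort B equals cohort A except that the deep-layer (adipose, muscle)
    strain distributions are scaled multiplicatively by ``effect``; for the
    lognormal family this shifts the log-mean by ln(effect), so the
    exceedance of B above any threshold T derived from A has the closed
    form ``lognormal_exceedance(mu + ln(effect), sigma, T)``.

    Returns ``(table_a, table_b)``.
    """
    if effect <= 0:
        raise ValueError("effect must be positive")
    base = {
        "epidermis": ("lognormal", (np.log(0.02), sigma), 5.0),
        "dermis": ("lognormal", (np.log(0.05), sigma), 50.0),
        "adipose": ("lognormal", (np.log(0.20), sigma), 200.0),
        "muscle": ("lognormal", (np.log(0.10), sigma), 300.0),
    }
    shifted = {
        name: (fam, ((params[0] + np.log(effect)) if name in ("adipose", "muscle") else params[0], params[1]), vol)
        for name, (fam, params, vol) in base.items()
    }
    spec_a = SyntheticFieldSpec(layers=base, n=n, seed=seed)
    spec_b = SyntheticFieldSpec(layers=shifted, n=n, seed=seed + 1)
    return generate_field(spec_a), generate_field(spec_b)
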