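"""Constitutive models for the tissue layers.

All soft tissues are compressible Neo-Hookean solids with strain energy

    W(F) = mu/2 (I1 - 3) - mu ln J + lam/2 (ln J)^2

where ``I1 = tr(F^T F)``, ``J = det F`` and ``lam``, ``mu`` are the Lame
parameters derived from Young's modulus ``E`` (kPa) and Poisson ratio
``nu``.  An optional Prony series describes stress relaxation; the default
analysis is quasi-static (relaxation factor g == 1), i.e. the instantaneous
hyperelastic response.

Units: moduli and stresses in kPa, lengths in mm, so forces come out in
kPa*mm^2 without conversion factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "MaterialParams",
    "DeformationState",
    "InvertedElementError",
    "lame_from_moduli",
    "moduli_from_lame",
    "deformation_state",
    "neo_hookean_energy",
    "pk1_stress",
    "pk1_tangent",
    "cauchy_from_pk1",
    "cauchy_stress",
    "prony_modulus",
    "reduce_stiffness",
]


class InvertedElementError(ValueError):
    """Raised when a deformation gradient has non-positive determinant."""


def lame_from_moduli(E: float, nu: float) -> Tuple[float, float]:
    """Convert (E, nu) to the Lame parameters (lam, mu).

    Raises ``ValueError`` for non-positive E and for ``nu >= 0.5``: the
    incompressible limit needs a mixed formulation, not a material constant.
    """
    if E <= 0.0:
        raise ValueError(f"Young's modulus must be positive, got {E}")
    if not (0.0 <= nu < 0.5):
        raise ValueError(
            f"Poisson ratio must lie in [0, 0.5), got {nu}; nu >= 0.5 is the "
            "incompressible limit and is not representable by Lame constants"
        )
    mu = E / (2.0 * (1.0 + nu))
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return lam, mu


def moduli_from_lame(lam: float, mu: float) -> Tuple[float, float]:
    """Inverse of :func:`lame_from_moduli`."""
    if mu <= 0.0:
        raise ValueError("mu must be positive")
    E = mu * (3.0 * lam + 2.0 * mu) / (lam + mu)
    nu = lam / (2.0 * (lam + mu))
    return E, nu


@dataclass(frozen=True)
class MaterialParams:
    """Elastic (and optional viscoelastic) constants of one tissue.

    Parameters
    ----------
    name : tissue label ("epidermis", ..., "bone", "sensor", or arbitrary).
    E : Young's modulus in kPa.
    nu : Poisson ratio, in [0, 0.5).
    prony : sequence of (gamma_i, tau_i) relaxation pairs; sum(gamma) < 1,
        tau > 0.  Empty by default (quasi-static analysis).
    is_linear : True for materials treated as linear elastic (bone, sensor);
        such materials are excluded from soft-tissue stiffness reduction.
    """

    name: str
    E: float
    nu: float
    prony: Tuple[Tuple[float, float], ...] = field(default_factory=tuple)
    is_linear: bool = False

    def __post_init__(self) -> None:
        lame_from_moduli(self.E, self.nu)  # validates E, nu
        gammas = [g for g, _ in self.prony]
        taus = [t for _, t in self.prony]
        if any(g < 0 for g in gammas) or sum(gammas) >= 1.0:
            raise ValueError("Prony gammas must be >= 0 with sum < 1")
        if any(t <= 0 for t in taus):
            raise ValueError("Prony time constants must be positive")
        object.__setattr__(self, "prony", tuple((float(g), float(t)) for g, t in self.prony))

    @property
    def lam(self) -> float:
        return lame_from_moduli(self.E, self.nu)[0]

    @property
    def mu(self) -> float:
        return lame_from_moduli(self.E, self.nu)[1]


@dataclass(frozen=True)
class DeformationState:
    """Point-wise kinematic state derived from a deformation gradient."""

    F: np.ndarray
    I1: float
    J: float

    @property
    def C(self) -> np.ndarray:
        return self.F.T @ self.F


def deformation_state(F: np.ndarray) -> DeformationState:
    """Build a :class:`DeformationState`, rejecting inverted configurations."""
    F = np.asarray(F, dtype=float)
    if F.shape != (3, 3):
        raise ValueError("deformation gradient must be 3x3")
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise InvertedElementError(f"det F = {J} <= 0 (inverted element)")
    I1 = float(np.trace(F.T @ F))
    return DeformationState(F=F, I1=I1, J=J)


def neo_hookean_energy(state: DeformationState, m: MaterialParams) -> float:
    """Strain energy density W (kPa) of the compressible Neo-Hookean law."""
    if state.J <= 0.0:
        raise InvertedElementError("det F <= 0")
    lnJ = np.log(state.J)
    return 0.5 * m.mu * (state.I1 - 3.0) - m.mu * lnJ + 0.5 * m.lam * lnJ * lnJ


def pk1_stress(state: DeformationState, m: MaterialParams) -> np.ndarray:
    """First Piola-Kirchhoff stress P = dW/dF = mu F + (lam ln J - mu) F^{-T}."""
    F = state.F
    if state.J <= 0.0:
        raise InvertedElementError("det F <= 0")
    FinvT = np.linalg.inv(F).T
    return m.mu * F + (m.lam * np.log(state.J) - m.mu) * FinvT


def pk1_tangent(state: DeformationState, m: MaterialParams) -> np.ndarray:
    """Material tangent A_{iJkL} = d P_{iJ} / d F_{kL} (shape (3,3,3,3)).

    For P = mu F + (lam ln J - mu) F^{-T}:

        A = mu I (x) I + lam F^{-T} (x) F^{-T}
            - (lam ln J - mu) * dF^{-T}/dF,
        with  d(F^{-T}_{iJ})/dF_{kL} = -F^{-1}_{Jk} F^{-1}_{Li}.
    """
    F = state.F
    Finv = np.linalg.inv(F)
    FinvT = Finv.T
    lnJ = np.log(state.J)
    A = m.mu * np.einsum("ik,JL->iJkL", np.eye(3), np.eye(3))
    A += m.lam * np.einsum("iJ,kL->iJkL", FinvT, FinvT)
    A += (m.mu - m.lam * lnJ) * np.einsum("Jk,Li->iJkL", Finv, Finv)
    return A


def cauchy_from_pk1(P: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Push forward a first Piola-Kirchhoff tensor: sigma = (1/J) P F^T."""
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise InvertedElementError(f"det F = {J} <= 0")
    sigma = (P @ F.T) / J
    return 0.5 * (sigma + sigma.T)  # symmetrize roundoff


def cauchy_stress(state: DeformationState, m: MaterialParams) -> np.ndarray:
    """Cauchy stress of the Neo-Hookean law at the given state."""
    return cauchy_from_pk1(pk1_stress(state, m), state.F)


def prony_modulus(t: float | np.ndarray, m: MaterialParams) -> float | np.ndarray:
    """Normalized relaxation factor g(t) = 1 - sum_i gamma_i (1 - exp(-t/tau_i)).

    ``g(0) = 1`` (instantaneous response) and ``g(inf) = 1 - sum(gamma)``
    (long-term response); g is monotonically non-increasing.  With no Prony
    terms g == 1 for all t, the quasi-static default.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0):
        raise ValueError("time must be non-negative")
    g = np.ones_like(t_arr)
    for gamma, tau in m.prony:
        g = g - gamma * (1.0 - np.exp(-t_arr / tau))
    return float(g) if np.isscalar(t) or t_arr.ndim == 0 else g


def reduce_stiffness(m: MaterialParams, fraction: float) -> MaterialParams:
    """Return a copy with Young's modulus reduced by ``fraction`` (e.g. 0.2).

    Only soft tissues may be softened; linear-elastic components (bone,
    sensor) raise ``ValueError``.  ``fraction == 0`` is the identity.
    """
    if fraction == 0.0:
        return m
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"stiffness reduction fraction must be in (0, 1), got {fraction}")
    if m.is_linear:
        raise ValueError(
            f"stiffness reduction applies to soft tissue only; {m.name!r} is linear-elastic"
        )
    return replace(m, E=(1.0 - fraction) * m.E)
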