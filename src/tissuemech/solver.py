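"""Nonlinear static axisymmetric finite elements for the layered model.

Formulation
-----------
Total-Lagrangian large-deformation kinematics on 6-node quadratic triangles
with 3-point Gauss quadrature (rank-sufficient; the mild under-integration
also relaxes volumetric stiffness at nu = 0.48).  The axisymmetric
deformation gradient is carried as the packed 5-vector

    F5 = (F_rR, F_rZ, F_zR, F_zZ, F_tt),   F_tt = 1 + u_r / R,

with J = det(F_inplane) * F_tt.  The compressible Neo-Hookean first
Piola-Kirchhoff stress and its analytic tangent close the Newton iteration;
the linearized systems are solved by sparse LU.

The indenter load is a uniform *follower* pressure over the surface facets
with r <= a (traction applied on the deformed surface); its geometric
tangent is formed per loaded edge by finite differencing the edge force.
Load stepping is adaptive: increments are halved on non-convergence and
grown 1.5x after two fast increments, within the configured bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .anatomy import AnatomyModel, LoadCase
from .materials import MaterialParams
from .meshing import Mesh

__all__ = [
    "SolverSettings",
    "SolutionField",
    "SolveError",
    "Constraints",
    "LoadPatch",
    "apply_boundary_conditions",
    "apply_load",
    "solve",
    "solve_rigid_punch",
    "postprocess_kinematics",
    "reaction_forces",
    "boundary_edges",
]


class SolveError(RuntimeError):
    """Non-convergence or element inversion; message carries diagnostics."""


@dataclass(frozen=True)
class SolverSettings:
    """Adaptive incrementation and Newton tolerances (static implicit)."""

    initial_increment: float = 0.05
    total_step: float = 1.0
    min_increment: float = 1e-6
    max_increment: float = 1.0
    max_increments: int = 1000
    newton_tol_residual: float = 1e-8  # relative to the external force norm
    newton_max_iter: int = 25

    def __post_init__(self) -> None:
        if not (0 < self.min_increment <= self.initial_increment <= self.max_increment <= self.total_step):
            raise ValueError("require min <= initial <= max <= total step")
        if self.newton_tol_residual <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class Constraints:
    """Dirichlet constraints: dof indices (2*node + comp) and target values
    at full load (scaled by the load factor during incrementation)."""

    dofs: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        order = np.argsort(self.dofs)
        self.dofs = np.asarray(self.dofs, dtype=np.int64)[order]
        self.values = np.asarray(self.values, dtype=float)[order]
        if len(np.unique(self.dofs)) != len(self.dofs):
            raise ValueError("duplicate constrained dofs")


@dataclass(frozen=True)
class LoadPatch:
    """Follower pressure over a set of quadratic surface edges."""

    edges: np.ndarray  # (n_edges, 3) node ids, ordered (end, mid, end)
    pressure: float  # kPa


@dataclass
class SolutionField:
    """Converged solution with per-element stress/strain tensors."""

    displacement: np.ndarray  # (nn, 2) in mm
    element_stress: np.ndarray  # (ne, 3, 3) Cauchy, kPa, basis (r, z, theta)
    element_strain: np.ndarray  # (ne, 3, 3) Hencky (logarithmic)
    element_J: np.ndarray  # (ne,) volume ratio
    converged: bool
    increments_used: int
    external_work: float  # kPa*mm^3
    stored_energy: float  # kPa*mm^3
    internal_force: np.ndarray  # (ndof,) at the final state
    external_force: np.ndarray  # (ndof,) at the final state
    residual_norm: float


# ---------------------------------------------------------------------------
# quadratic triangle reference element
# ---------------------------------------------------------------------------

_GP = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
_GW = np.array([1 / 6, 1 / 6, 1 / 6])


def _shape(xi: float, eta: float) -> Tuple[np.ndarray, np.ndarray]:
    l1 = 1.0 - xi - eta
    N = np.array(
        [l1 * (2 * l1 - 1), xi * (2 * xi - 1), eta * (2 * eta - 1), 4 * l1 * xi, 4 * xi * eta, 4 * eta * l1]
    )
    dN = np.array(
        [
            [1 - 4 * l1, 1 - 4 * l1],
            [4 * xi - 1, 0.0],
            [0.0, 4 * eta - 1],
            [4 * (l1 - xi), -4 * xi],
            [4 * eta, 4 * xi],
            [-4 * eta, 4 * (l1 - eta)],
        ]
    )
    return N, dN


class _ElementData:
    """Precomputed reference-configuration quantities per Gauss point."""

    def __init__(self, mesh: Mesh):
        X = mesh.nodes[mesh.elements]  # (ne, 6, 2)
        self.conn = mesh.elements
        self.N = []
        self.dNdX = []
        self.wdet = []  # w * detJ * 2*pi*R_gp  (reference ring measure)
        self.Rgp = []
        for (xi, eta), w in zip(_GP, _GW):
            N, dN = _shape(xi, eta)
            Jmat = np.einsum("eai,ad->eid", X, dN)  # (ne, 2, 2)
            det = Jmat[:, 0, 0] * Jmat[:, 1, 1] - Jmat[:, 0, 1] * Jmat[:, 1, 0]
            if np.any(det <= 0):
                raise SolveError("mesh contains an element with non-positive Jacobian")
            inv = np.empty_like(Jmat)
            inv[:, 0, 0] = Jmat[:, 1, 1]
            inv[:, 1, 1] = Jmat[:, 0, 0]
            inv[:, 0, 1] = -Jmat[:, 0, 1]
            inv[:, 1, 0] = -Jmat[:, 1, 0]
            inv /= det[:, None, None]
            dNdX = np.einsum("ad,edD->eaD", dN, inv)  # (ne, 6, 2)
            R = X[:, :, 0] @ N
            self.N.append(N)
            self.dNdX.append(dNdX)
            self.Rgp.append(R)
            self.wdet.append(w * det * 2.0 * np.pi * R)
        # per-gp B matrices (ne, 5, 12), constant in the reference config
        self.B = []
        ne = len(self.conn)
        for gp in range(3):
            B = np.zeros((ne, 5, 12))
            dNdX = self.dNdX[gp]
            N = self.N[gp]
            for a in range(6):
                B[:, 0, 2 * a] = dNdX[:, a, 0]
                B[:, 1, 2 * a] = dNdX[:, a, 1]
                B[:, 2, 2 * a + 1] = dNdX[:, a, 0]
                B[:, 3, 2 * a + 1] = dNdX[:, a, 1]
                B[:, 4, 2 * a] = N[a] / self.Rgp[gp]
            self.B.append(B)
        # scatter indices for assembly
        dofmap = np.empty((ne, 12), dtype=np.int64)
        dofmap[:, 0::2] = 2 * self.conn
        dofmap[:, 1::2] = 2 * self.conn + 1
        self.dofmap = dofmap
        self.rows = np.repeat(dofmap, 12, axis=1).ravel()
        self.cols = np.tile(dofmap, (1, 12)).ravel()


def _element_materials(mesh: Mesh, model: AnatomyModel) -> Tuple[np.ndarray, np.ndarray]:
    mats: Dict[str, MaterialParams] = {ly.name: ly.material for ly in model.layers}
    mu = np.empty(mesh.n_elements)
    lam = np.empty(mesh.n_elements)
    for name, m in mats.items():
        sel = mesh.layer_tag.astype(str) == name
        mu[sel] = m.mu
        lam[sel] = m.lam
    untagged = ~np.isin(mesh.layer_tag.astype(str), list(mats))
    if untagged.any():
        raise SolveError(f"mesh layers {set(mesh.layer_tag[untagged])} missing from the model")
    return mu, lam


def _state(ed: _ElementData, U: np.ndarray, gp: int):
    """Packed kinematics at one Gauss point for all elements."""
    ue = U.reshape(-1, 2)[ed.conn]  # (ne, 6, 2)
    dNdX = ed.dNdX[gp]
    G = np.einsum("eai,eaJ->eiJ", ue, dNdX)  # displacement gradient (2x2)
    F = G.copy()
    F[:, 0, 0] += 1.0
    F[:, 1, 1] += 1.0
    Ftt = 1.0 + (ue[:, :, 0] @ ed.N[gp]) / ed.Rgp[gp]
    detp = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
    J = detp * Ftt
    return F, Ftt, detp, J


def _pk1_packed(F, Ftt, detp, J, mu, lam):
    """P5 and the packed 5x5 tangent for the Neo-Hookean law (vectorized)."""
    ne = len(J)
    Finv = np.empty_like(F)
    Finv[:, 0, 0] = F[:, 1, 1]
    Finv[:, 1, 1] = F[:, 0, 0]
    Finv[:, 0, 1] = -F[:, 0, 1]
    Finv[:, 1, 0] = -F[:, 1, 0]
    Finv /= detp[:, None, None]
    lnJ = np.log(J)
    coef = lam * lnJ - mu  # (ne,)

    F5 = np.stack([F[:, 0, 0], F[:, 0, 1], F[:, 1, 0], F[:, 1, 1], Ftt], axis=1)
    G5 = np.stack([Finv[:, 0, 0], Finv[:, 1, 0], Finv[:, 0, 1], Finv[:, 1, 1], 1.0 / Ftt], axis=1)
    P5 = mu[:, None] * F5 + coef[:, None] * G5

    A = np.zeros((ne, 5, 5))
    A += mu[:, None, None] * np.eye(5)
    A += lam[:, None, None] * np.einsum("ea,eb->eab", G5, G5)
    # -coef * D, D_(iJ)(kL) = Finv[J,k] Finv[L,i] on the in-plane 4x4 block,
    # with packed index alpha = 2*i + J matching the F5 ordering
    Dp = np.empty((ne, 4, 4))
    for i in range(2):
        for Jx in range(2):
            for k in range(2):
                for Lx in range(2):
                    Dp[:, 2 * i + Jx, 2 * k + Lx] = Finv[:, Jx, k] * Finv[:, Lx, i]
    A[:, :4, :4] -= coef[:, None, None] * Dp
    A[:, 4, 4] -= coef / Ftt**2
    return P5, A


def _internal_and_tangent(ed: _ElementData, mu, lam, U, need_tangent=True):
    ndof = 2 * (int(ed.conn.max()) + 1)
    fint = np.zeros(ndof)
    Kes = np.zeros((len(ed.conn), 12, 12)) if need_tangent else None
    minJ = np.inf
    for gp in range(3):
        F, Ftt, detp, J = _state(ed, U, gp)
        minJ = min(minJ, float(J.min()))
        if minJ <= 0:
            raise _Inversion()
        P5, A = _pk1_packed(F, Ftt, detp, J, mu, lam)
        w = ed.wdet[gp]
        B = ed.B[gp]
        fe = np.einsum("eab,ea,e->eb", B, P5, w)
        np.add.at(fint, ed.dofmap, fe)
        if need_tangent:
            Kes += np.einsum("eab,eac,ecd,e->ebd", B, A, B, w, optimize=True)
    if need_tangent:
        K = sp.coo_matrix((Kes.ravel(), (ed.rows, ed.cols)), shape=(ndof, ndof)).tocsr()
        return fint, K, minJ
    return fint, None, minJ


class _Inversion(Exception):
    pass


# ---------------------------------------------------------------------------
# boundary conditions and loading
# ---------------------------------------------------------------------------

_TOL = 1e-9


def boundary_edges(mesh: Mesh) -> np.ndarray:
    """All exterior quadratic edges as (end, mid, end) node triples."""
    counts: Dict[Tuple[int, int], Tuple[int, int, int]] = {}
    seen: Dict[Tuple[int, int], int] = {}
    for conn in mesh.elements:
        for (a, b, m) in ((conn[0], conn[1], conn[3]), (conn[1], conn[2], conn[4]), (conn[2], conn[0], conn[5])):
            key = (a, b) if a < b else (b, a)
            seen[key] = seen.get(key, 0) + 1
            counts[key] = (a, m, b)
    return np.array([trip for key, trip in counts.items() if seen[key] == 1], dtype=np.int64)


def apply_boundary_conditions(mesh: Mesh, mode: str = "default") -> Constraints:
    """Build the Dirichlet set.

    ``default``: basal surface fully fixed, outer radial boundary and the
    symmetry axis constrained against radial motion.
    ``confined``: uniaxial-strain column — base fixed vertically only, axis
    and outer wall roller-constrained radially (benchmark problems).
    """
    r, z = mesh.nodes[:, 0], mesh.nodes[:, 1]
    on_axis = np.abs(r) < _TOL
    on_outer = np.abs(r - mesh.domain_radius) < _TOL
    on_base = np.abs(z - mesh.depth) < _TOL
    dofs, vals = [], []

    def fix(nodes_mask, comp):
        idx = np.nonzero(nodes_mask)[0]
        dofs.append(2 * idx + comp)
        vals.append(np.zeros(len(idx)))

    if mode == "default":
        fix(on_base, 0)
        fix(on_base, 1)
        fix(on_axis & ~on_base, 0)
        fix(on_outer & ~on_base, 0)
    elif mode == "confined":
        fix(on_base, 1)
        fix(on_axis, 0)
        fix(on_outer, 0)
    else:
        raise ValueError(f"unknown boundary-condition mode {mode!r}")
    dof_arr = np.concatenate(dofs)
    dof_arr, keep = np.unique(dof_arr, return_index=True)
    return Constraints(dofs=dof_arr, values=np.concatenate(vals)[keep])


def apply_load(mesh: Mesh, lc: LoadCase, patch_radius: float | None = None) -> LoadPatch:
    """Uniform normal pressure over the surface facets with r <= patch radius."""
    if lc.contact_mode not in ("traction_patch", "rigid_punch"):
        raise ValueError(f"unknown contact mode {lc.contact_mode!r}")
    a = mesh.indenter_radius if patch_radius is None else patch_radius
    if a > mesh.domain_radius + _TOL:
        raise ValueError("indenter radius exceeds the domain radius")
    edges = boundary_edges(mesh)
    z = mesh.nodes[:, 1]
    r = mesh.nodes[:, 0]
    on_surf = np.all(np.abs(z[edges]) < _TOL, axis=1)
    mid_r = r[edges[:, 1]]
    sel = on_surf & (mid_r < a + _TOL)
    chosen = edges[sel]
    # orient each edge with increasing r so the follower force points into z > 0
    flip = r[chosen[:, 0]] > r[chosen[:, 2]]
    chosen[flip] = chosen[flip][:, ::-1]
    return LoadPatch(edges=chosen, pressure=lc.pressure)


_EGP = np.array([-np.sqrt(3 / 5), 0.0, np.sqrt(3 / 5)])
_EGW = np.array([5 / 9, 8 / 9, 5 / 9])


def _edge_force(x: np.ndarray, p: float) -> np.ndarray:
    """Follower-pressure nodal force of one quadratic edge (deformed coords
    x: (3, 2), ordered with increasing r).  Returns (3, 2)."""
    f = np.zeros((3, 2))
    for xi, w in zip(_EGP, _EGW):
        N = np.array([0.5 * xi * (xi - 1.0), 1.0 - xi * xi, 0.5 * xi * (xi + 1.0)])
        dN = np.array([xi - 0.5, -2.0 * xi, xi + 0.5])
        r = N @ x[:, 0]
        dr = dN @ x[:, 0]
        dz = dN @ x[:, 1]
        c = 2.0 * np.pi * p * w * r
        f[:, 0] += -c * N * dz
        f[:, 1] += c * N * dr
    return f


def _external_force(mesh: Mesh, load: LoadPatch | None, U: np.ndarray, scale: float):
    """Assembled follower force vector and its tangent contribution triplets."""
    ndof = 2 * mesh.n_nodes
    fext = np.zeros(ndof)
    rows, cols, vals = [], [], []
    if load is None or load.pressure == 0.0 or scale == 0.0:
        return fext, (rows, cols, vals)
    p = load.pressure * scale
    Unod = U.reshape(-1, 2)
    for trip in load.edges:
        x = mesh.nodes[trip] + Unod[trip]
        f = _edge_force(x, p)
        edofs = np.array([2 * trip[0], 2 * trip[0] + 1, 2 * trip[1], 2 * trip[1] + 1, 2 * trip[2], 2 * trip[2] + 1])
        np.add.at(fext, edofs, f.ravel())
        # geometric load stiffness d f / d u by forward differences
        h = 1e-7 * max(1.0, float(np.abs(x).max()))
        Ke = np.empty((6, 6))
        for j in range(6):
            xp = x.copy()
            xp[j // 2, j % 2] += h
            Ke[:, j] = (_edge_force(xp, p).ravel() - f.ravel()) / h
        rows.extend(np.repeat(edofs, 6))
        cols.extend(np.tile(edofs, 6))
        vals.extend(Ke.ravel())
    return fext, (rows, cols, vals)


# ---------------------------------------------------------------------------
# Newton / incrementation driver
# ---------------------------------------------------------------------------


def solve(
    mesh: Mesh,
    model: AnatomyModel,
    load: LoadPatch | None = None,
    settings: SolverSettings | None = None,
    constraints: Constraints | None = None,
) -> SolutionField:
    """Solve the static large-deformation problem by adaptive load stepping.

    Both the follower pressure and any non-zero prescribed displacements in
    ``constraints`` are ramped by the load factor.  Raises :class:`SolveError`
    if the increment size falls below the configured minimum.
    """
    settings = settings or SolverSettings()
    constraints = constraints if constraints is not None else apply_boundary_conditions(mesh)
    ed = _ElementData(mesh)
    mu, lam = _element_materials(mesh, model)
    ndof = 2 * mesh.n_nodes
    free = np.setdiff1d(np.arange(ndof), constraints.dofs)

    U = np.zeros(ndof)
    t = 0.0
    dt = settings.initial_increment
    increments = 0
    fast_streak = 0
    work = 0.0
    fext_prev = np.zeros(ndof)
    last_res = np.nan

    zero_load = (load is None or load.pressure == 0.0) and not np.any(constraints.values)
    if zero_load:
        fint, _, _ = _internal_and_tangent(ed, mu, lam, U, need_tangent=False)
        return _package(mesh, ed, mu, lam, U, True, 1, 0.0, np.zeros(ndof), fint, 0.0)

    while t < settings.total_step - 1e-12:
        if increments >= settings.max_increments:
            raise SolveError(f"exceeded {settings.max_increments} increments at t={t:.4g}")
        t_try = min(t + dt, settings.total_step)
        frac = t_try / settings.total_step
        ok, U_new, fext_new, res = _newton(
            ed, mesh, mu, lam, U, load, frac, free, constraints, settings,
            target_cvals=constraints.values * frac,
        )
        increments += 1
        if ok:
            work += 0.5 * float((fext_prev + fext_new) @ (U_new - U))
            U, fext_prev = U_new, fext_new
            t = t_try
            last_res = res
            fast_streak = fast_streak + 1
            if fast_streak >= 2:
                dt = min(dt * 1.5, settings.max_increment)
                fast_streak = 0
        else:
            fast_streak = 0
            dt *= 0.5
            if dt < settings.min_increment:
                raise SolveError(
                    f"increment fell below {settings.min_increment:g} at t={t:.4g} "
                    f"(last residual {res:.3e})"
                )
    fint, _, _ = _internal_and_tangent(ed, mu, lam, U, need_tangent=False)
    return _package(mesh, ed, mu, lam, U, True, increments, work, fext_prev, fint, last_res)


def _newton(ed, mesh, mu, lam, U, load, scale, free, constraints, settings, target_cvals=None):
    """One load increment; returns (converged, U, fext, last_residual_norm).

    ``U`` must be a valid (non-inverted) state; prescribed-displacement
    increments are driven through the consistent K_fc * du_c coupling term
    rather than by jumping the constrained dofs, so thin stiff layers are
    never handed an inverted trial configuration.
    """
    U = U.copy()
    if target_cvals is None:
        target_cvals = U[constraints.dofs]
    cdofs = constraints.dofs
    uscale = max(1.0, float(np.abs(target_cvals).max()) if len(target_cvals) else 1.0)
    res_norm = np.inf
    prev_norm = np.inf
    for it in range(settings.newton_max_iter):
        try:
            fint, K, _ = _internal_and_tangent(ed, mu, lam, U)
        except _Inversion:
            return False, U, None, res_norm
        fext, (lr, lcidx, lv) = _external_force(mesh, load, U, scale)
        R = fint - fext
        dUc = target_cvals - U[cdofs]
        # force scale: external load norm or, for displacement-driven
        # problems, the reaction norm at the constrained dofs
        ref = max(np.linalg.norm(fext[free]), np.linalg.norm(R[cdofs]), 1e-12)
        res_norm = np.linalg.norm(R[free])
        constraints_met = (np.abs(dUc).max() if len(dUc) else 0.0) <= 1e-10 * uscale
        stagnated = res_norm > 0.99 * prev_norm and res_norm <= 1e-6 * ref
        if constraints_met and (res_norm <= settings.newton_tol_residual * ref or stagnated):
            # stagnation below a loose floor means the iteration hit the
            # roundoff limit of the (ill-conditioned) layered stiffness
            return True, U, fext, res_norm
        prev_norm = res_norm
        if lv:
            K = (K - sp.coo_matrix((lv, (lr, lcidx)), shape=K.shape).tocsr()).tocsc()
        else:
            K = K.tocsc()
        try:
            rhs = -(R[free] + K[free][:, cdofs] @ dUc)
            dU = spla.spsolve(K[free][:, free], rhs)
        except Exception:
            return False, U, None, res_norm
        if not np.all(np.isfinite(dU)):
            return False, U, None, res_norm
        # damped step: take the largest fraction of (dU, dUc) that keeps
        # every element non-inverted; adaptivity handles the rest
        alpha = 1.0
        accepted = False
        for _ in range(6):
            U_try = U.copy()
            U_try[free] += alpha * dU
            U_try[cdofs] += alpha * dUc
            try:
                _internal_and_tangent(ed, mu, lam, U_try, need_tangent=False)
            except _Inversion:
                alpha *= 0.5
                continue
            accepted = True
            break
        if not accepted:
            return False, U, None, res_norm
        U = U_try
    return False, U, None, res_norm


def _package(mesh, ed, mu, lam, U, converged, increments, work, fext, fint, res):
    stress, strain, Jel = postprocess_kinematics(mesh, U, mu, lam, ed)
    energy = _stored_energy(ed, mu, lam, U)
    return SolutionField(
        displacement=U.reshape(-1, 2),
        element_stress=stress,
        element_strain=strain,
        element_J=Jel,
        converged=converged,
        increments_used=increments,
        external_work=work,
        stored_energy=energy,
        internal_force=fint,
        external_force=fext,
        residual_norm=float(res) if np.isfinite(res) else 0.0,
    )


def _stored_energy(ed, mu, lam, U) -> float:
    E = 0.0
    for gp in range(3):
        F, Ftt, detp, J = _state(ed, U, gp)
        I1 = F[:, 0, 0] ** 2 + F[:, 0, 1] ** 2 + F[:, 1, 0] ** 2 + F[:, 1, 1] ** 2 + Ftt**2
        lnJ = np.log(J)
        W = 0.5 * mu * (I1 - 3.0) - mu * lnJ + 0.5 * lam * lnJ**2
        E += float(np.sum(W * ed.wdet[gp]))
    return E


def postprocess_kinematics(mesh: Mesh, U: np.ndarray, mu=None, lam=None, ed: _ElementData | None = None):
    """Per-element Cauchy stress, Hencky strain and J from a displacement.

    Gauss-point tensors are volume-averaged per element.  Returns
    ``(stress (ne,3,3), strain (ne,3,3), J (ne,))`` in the (r, z, theta)
    basis; stress requires per-element ``mu``/``lam``.
    """
    ed = ed or _ElementData(mesh)
    U = np.asarray(U, dtype=float).ravel()
    ne = len(ed.conn)
    stress = np.zeros((ne, 3, 3))
    strain = np.zeros((ne, 3, 3))
    Jacc = np.zeros(ne)
    wsum = np.zeros(ne)
    for gp in range(3):
        F, Ftt, detp, J = _state(ed, U, gp)
        if np.any(J <= 0):
            raise SolveError("inverted element in postprocessing")
        w = ed.wdet[gp]
        wsum += w
        Jacc += w * J
        # Hencky strain: 1/2 log(F^T F), via eigendecomposition of the 2x2 block
        C00 = F[:, 0, 0] ** 2 + F[:, 1, 0] ** 2
        C11 = F[:, 0, 1] ** 2 + F[:, 1, 1] ** 2
        C01 = F[:, 0, 0] * F[:, 0, 1] + F[:, 1, 0] * F[:, 1, 1]
        tr = C00 + C11
        disc = np.sqrt(np.maximum((C00 - C11) ** 2 + 4 * C01**2, 0.0))
        e1, e2 = 0.5 * (tr + disc), 0.5 * (tr - disc)
        if np.any(e2 <= 0):
            raise SolveError("non-SPD C encountered in postprocessing")
        # eigenvectors of the symmetric 2x2 [C00 C01; C01 C11]
        theta = 0.5 * np.arctan2(2 * C01, C00 - C11)
        c, s = np.cos(theta), np.sin(theta)
        l1, l2 = 0.5 * np.log(e1), 0.5 * np.log(e2)
        err = l1 * c**2 + l2 * s**2
        ezz = l1 * s**2 + l2 * c**2
        erz = (l1 - l2) * c * s
        strain[:, 0, 0] += w * err
        strain[:, 1, 1] += w * ezz
        strain[:, 0, 1] += w * erz
        strain[:, 1, 0] += w * erz
        strain[:, 2, 2] += w * np.log(Ftt)
        if mu is not None:
            P5, _ = _pk1_packed(F, Ftt, detp, J, mu, lam)
            # sigma = (1/J) P F^T on the in-plane block; tt: (1/J) P_tt F_tt
            Pm = P5[:, :4].reshape(ne, 2, 2)
            sig = np.einsum("eiJ,ekJ->eik", Pm, F) / J[:, None, None]
            sig = 0.5 * (sig + sig.transpose(0, 2, 1))
            stress[:, :2, :2] += w[:, None, None] * sig
            stress[:, 2, 2] += w * P5[:, 4] * Ftt / J
    strain /= wsum[:, None, None]
    stress /= wsum[:, None, None]
    return stress, strain, Jacc / wsum


def reaction_forces(mesh: Mesh, solution: SolutionField, constraints: Constraints) -> np.ndarray:
    """Reaction vector (ndof,) = internal minus external force at the
    constrained dofs; zero elsewhere (residual) up to solver tolerance."""
    R = solution.internal_force - solution.external_force
    out = np.zeros_like(R)
    out[constraints.dofs] = R[constraints.dofs]
    return out


def solve_rigid_punch(
    mesh: Mesh,
    model: AnatomyModel,
    pressure: float,
    settings: SolverSettings | None = None,
    reaction_tol: float = 1e-3,
) -> SolutionField:
    """Frictionless rigid flat punch under load control.

    The surface nodes with r <= a are driven downward (radial motion free,
    i.e. frictionless) by displacement continuation, warm-starting each
    depth from the previous converged state, until the punch reaction
    balances pressure * pi * a^2; the final depth is located by secant
    iteration on the reaction-depth curve.
    """
    settings = settings or SolverSettings()
    base = apply_boundary_conditions(mesh)
    if pressure == 0.0:
        return solve(mesh, model, load=None, settings=settings, constraints=base)
    r, z = mesh.nodes[:, 0], mesh.nodes[:, 1]
    punch_nodes = np.nonzero((np.abs(z) < _TOL) & (r <= mesh.indenter_radius + _TOL))[0]
    punch_dofs = 2 * punch_nodes + 1
    target = pressure * np.pi * mesh.indenter_radius**2

    ed = _ElementData(mesh)
    mu, lam = _element_materials(mesh, model)
    ndof = 2 * mesh.n_nodes
    cons = Constraints(dofs=np.concatenate([base.dofs, punch_dofs]),
                       values=np.concatenate([base.values, np.ones(len(punch_dofs))]))
    free = np.setdiff1d(np.arange(ndof), cons.dofs)
    punch_pos = np.searchsorted(cons.dofs, np.sort(punch_dofs))

    U = np.zeros(ndof)
    increments = 0

    def advance(U, depth):
        """Newton at a prescribed depth, warm-started from U."""
        target = np.zeros(len(cons.dofs))
        target[punch_pos] = depth
        return _newton(ed, mesh, mu, lam, U, None, 1.0, free, cons, settings, target_cvals=target)

    # continuation: grow the depth until the reaction brackets the target
    E0 = model.layers[0].material.E
    d = max(target / (2.0 * mesh.indenter_radius * E0), 1e-3)
    dd = d
    depth_hist, reac_hist = [0.0], [0.0]
    while True:
        if increments > settings.max_increments:
            raise SolveError("rigid punch: exceeded the increment budget")
        ok, U_new, _, res = advance(U, d)
        increments += 1
        if not ok:
            dd *= 0.5
            d = depth_hist[-1] + dd
            if dd < settings.min_increment:
                raise SolveError(f"rigid punch: increment collapsed (residual {res:.3e})")
            continue
        U = U_new
        fint, _, _ = _internal_and_tangent(ed, mu, lam, U, need_tangent=False)
        reac = float(fint[punch_dofs].sum())
        depth_hist.append(d)
        reac_hist.append(reac)
        if reac >= target:
            break
        slope = (reac_hist[-1] - reac_hist[-2]) / (depth_hist[-1] - depth_hist[-2])
        dd = min(1.6 * dd, max(0.25 * dd, 0.8 * (target - reac) / max(slope, 1e-12)))
        d += dd

    # secant refinement inside the bracket
    d_lo, f_lo = depth_hist[-2], reac_hist[-2]
    d_hi, f_hi = depth_hist[-1], reac_hist[-1]
    for _ in range(30):
        if abs(reac_hist[-1] - target) <= reaction_tol * target:
            break
        d = d_lo + (target - f_lo) * (d_hi - d_lo) / (f_hi - f_lo)
        ok, U_new, _, res = advance(U, d)
        increments += 1
        if not ok:
            raise SolveError("rigid punch: refinement step failed")
        U = U_new
        fint, _, _ = _internal_and_tangent(ed, mu, lam, U, need_tangent=False)
        reac = float(fint[punch_dofs].sum())
        depth_hist.append(d)
        reac_hist.append(reac)
        if reac < target:
            d_lo, f_lo = d, reac
        else:
            d_hi, f_hi = d, reac
    else:
        raise SolveError("rigid punch reaction iteration did not converge")

    fint, _, _ = _internal_and_tangent(ed, mu, lam, U, need_tangent=False)
    return _package(mesh, ed, mu, lam, U, True, increments, np.nan, np.zeros(ndof), fint, 0.0)
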