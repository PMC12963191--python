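import numpy as np
import pytest

from conftest import single_layer_model
from tissuemech.anatomy import LoadCase, builtin_model
from tissuemech.benchmarks import circular_load_halfspace_benchmark, uniaxial_strain_benchmark
from tissuemech.materials import MaterialParams
from tissuemech.meshing import build_mesh
from tissuemech.solver import (
    Constraints,
    SolveError,
    SolverSettings,
    apply_boundary_conditions,
    apply_load,
    boundary_edges,
    postprocess_kinematics,
    reaction_forces,
    solve,
    solve_rigid_punch,
)


class TestBoundaryConditions:
    def test_base_fully_fixed(self, mesh_m1_coarse):
        cons = apply_boundary_conditions(mesh_m1_coarse)
        base_nodes = np.nonzero(np.abs(mesh_m1_coarse.nodes[:, 1] - mesh_m1_coarse.depth) < 1e-9)[0]
        assert len(base_nodes) > 0
        for n in base_nodes:
            assert 2 * n in cons.dofs and 2 * n + 1 in cons.dofs

    def test_no_rigid_body_modes(self):
        """Constrained stiffness is positive definite on a coarse mesh."""
        from tissuemech.solver import _element_materials, _ElementData, _internal_and_tangent

        model = single_layer_model(E=10, nu=0.3, thickness=5, radius=10, indenter=5)
        mesh = build_mesh(model, "coarse", layer_divisions={"slab": 3})
        cons = apply_boundary_conditions(mesh)
        ed = _ElementData(mesh)
        mu, lam = _element_materials(mesh, model)
        _, K, _ = _internal_and_tangent(ed, mu, lam, np.zeros(2 * mesh.n_nodes))
        free = np.setdiff1d(np.arange(2 * mesh.n_nodes), cons.dofs)
        Kff = K.tocsc()[free][:, free].toarray()
        eig = np.linalg.eigvalsh(0.5 * (Kff + Kff.T))
        assert eig.min() > 0

    def test_interfaces_are_conforming(self, mesh_m1_coarse):
        """Tie condition: adjacent layers share interface nodes (the mesh has
        exactly one node per interface location, so element counts touching
        an interface node span two layer tags)."""
        coords = [tuple(np.round(xy, 9)) for xy in mesh_m1_coarse.nodes]
        assert len(coords) == len(set(coords))  # no duplicated nodes anywhere


class TestLoad:
    def test_reference_resultant(self, mesh_m1_coarse):
        """Follower traction integrates to p pi a^2 in the reference state."""
        from tissuemech.solver import _external_force

        load = apply_load(mesh_m1_coarse, LoadCase(pressure=10.0))
        fext, _ = _external_force(mesh_m1_coarse, load, np.zeros(2 * mesh_m1_coarse.n_nodes), 1.0)
        assert fext[1::2].sum() == pytest.approx(10.0 * np.pi * 25.0, rel=1e-12)
        assert abs(fext[0::2].sum()) < 1e-9 * abs(fext[1::2].sum())

    def test_zero_pressure_zero_solution(self, model1, mesh_m1_coarse):
        load = apply_load(mesh_m1_coarse, LoadCase(pressure=0.0))
        sol = solve(mesh_m1_coarse, model1, load=load)
        assert sol.converged and sol.increments_used == 1
        assert np.allclose(sol.displacement, 0.0)
        assert np.allclose(sol.element_stress, 0.0, atol=1e-12)

    def test_small_load_linearity(self):
        """Doubling a tiny pressure doubles the peak displacement within 2%."""
        model = single_layer_model(E=100, nu=0.3, thickness=20, radius=20, indenter=5)
        mesh = build_mesh(model, "coarse", layer_divisions={"slab": 5})
        w = []
        for p in (1e-4 * 100, 2e-4 * 100):
            sol = solve(mesh, model, load=apply_load(mesh, LoadCase(pressure=p)))
            w.append(np.abs(sol.displacement[:, 1]).max())
        assert w[1] / w[0] == pytest.approx(2.0, rel=0.02)

    def test_unknown_mode_rejected(self, mesh_m1_coarse):
        with pytest.raises(Exception):
            apply_load(mesh_m1_coarse, LoadCase(pressure=1.0, contact_mode="sticky"))


class TestPatchTest:
    def test_constant_strain_reproduced(self):
        """Dirichlet data from a homogeneous deformation is reproduced exactly
        (to solver tolerance) at interior nodes."""
        model = single_layer_model(E=10, nu=0.3, thickness=6, radius=12)
        mesh = build_mesh(model, "coarse", layer_divisions={"slab": 3})
        c, d = -0.02, -0.05  # u_r = c R, u_z = d Z  -> F = diag(1+c, 1+d, 1+c)
        r, z = mesh.nodes[:, 0], mesh.nodes[:, 1]
        on_bnd = (
            (np.abs(r) < 1e-9)
            | (np.abs(r - mesh.domain_radius) < 1e-9)
            | (np.abs(z) < 1e-9)
            | (np.abs(z - mesh.depth) < 1e-9)
        )
        idx = np.nonzero(on_bnd)[0]
        dofs = np.concatenate([2 * idx, 2 * idx + 1])
        vals = np.concatenate([c * r[idx], d * z[idx]])
        sol = solve(mesh, model, load=None, constraints=Constraints(dofs=dofs, values=vals))
        exact = np.column_stack([c * r, d * z])
        assert np.allclose(sol.displacement, exact, atol=1e-8)
        stress, strain, J = postprocess_kinematics(mesh, sol.displacement)
        assert np.allclose(strain[:, 0, 0], np.log(1 + c), atol=1e-9)
        assert np.allclose(strain[:, 1, 1], np.log(1 + d), atol=1e-9)
        assert np.allclose(J, (1 + c) ** 2 * (1 + d), atol=1e-9)


class TestConfinedCompressionBenchmark:
    @pytest.mark.parametrize("E,nu,p", [(10.0, 0.3, 2.0), (2.0, 0.48, 1.0)])
    def test_matches_scalar_oracle(self, E, nu, p):
        """FEM uniaxial-strain response vs bracketed root-finding, 0.5%."""
        mat = MaterialParams("slab", E=E, nu=nu)
        model = single_layer_model(E=E, nu=nu, thickness=8, radius=16)
        mesh = build_mesh(model, "coarse", layer_divisions={"slab": 4})
        cons = apply_boundary_conditions(mesh, mode="confined")
        sol = solve(mesh, model, load=apply_load(mesh, LoadCase(pressure=p)), constraints=cons)
        J_ref, sigma_ref, eps_ref = uniaxial_strain_benchmark(mat, p)
        assert np.allclose(sol.element_J, J_ref, rtol=5e-3)
        assert np.allclose(sol.element_stress[:, 1, 1], sigma_ref[1, 1], rtol=5e-3)
        assert np.allclose(sol.element_strain[:, 1, 1], eps_ref[1, 1], rtol=5e-3)
        # Hencky eps_zz equals ln J for uniaxial strain
        assert np.allclose(sol.element_strain[:, 1, 1], np.log(sol.element_J), atol=1e-9)


class TestHalfspaceBenchmark:
    def test_center_settlement(self):
        """Low-load circular pressure on a deep homogeneous domain matches
        w0 = 2 p a (1 - nu^2)/E within the 10% finite-domain tolerance."""
        E, nu, p, a = 100.0, 0.3, 0.05, 5.0
        model = single_layer_model(E=E, nu=nu, thickness=200.0, radius=200.0, indenter=a)
        mesh = build_mesh(model, "medium")
        sol = solve(mesh, model, load=apply_load(mesh, LoadCase(pressure=p)))
        center = np.nonzero((np.abs(mesh.nodes[:, 0]) < 1e-9) & (np.abs(mesh.nodes[:, 1]) < 1e-9))[0][0]
        w0 = circular_load_halfspace_benchmark(E, nu, p, a)
        assert sol.displacement[center, 1] == pytest.approx(w0, rel=0.10)


class TestEquilibriumAndEnergy:
    def test_reactions_balance_load(self, model1, mesh_m1_coarse, solved_m1_coarse):
        """Sum of constrained reactions equals the applied load (rel 1e-6)."""
        sol = solved_m1_coarse.solution
        cons = apply_boundary_conditions(mesh_m1_coarse)
        reac = reaction_forces(mesh_m1_coarse, sol, cons)
        fz = sol.external_force[1::2].sum()
        assert reac[1::2].sum() == pytest.approx(-fz, rel=1e-6)

    def test_external_work_vs_stored_energy(self, solved_m1_coarse):
        """Elastic quasi-static loading: path work matches stored energy ~1%."""
        sol = solved_m1_coarse.solution
        assert sol.external_work >= sol.stored_energy * 0.99
        assert sol.external_work == pytest.approx(sol.stored_energy, rel=0.01)

    def test_near_incompressibility(self, mesh_m1_coarse, solved_m1_coarse):
        """ROI-average J stays within [0.95, 1.05] at 10 kPa with nu=0.48."""
        sol = solved_m1_coarse.solution
        m = mesh_m1_coarse.roi_mask
        Jbar = np.average(sol.element_J[m], weights=mesh_m1_coarse.element_volume[m])
        assert 0.95 <= Jbar <= 1.05


class TestPostprocess:
    def test_rigid_translation_strain_free(self, mesh_m1_coarse):
        U = np.zeros((mesh_m1_coarse.n_nodes, 2))
        U[:, 1] = 0.37  # uniform axial shift
        stress, strain, J = postprocess_kinematics(mesh_m1_coarse, U)
        assert np.allclose(strain, 0.0, atol=1e-12)
        assert np.allclose(J, 1.0, atol=1e-12)

    def test_stress_symmetry(self, solved_m1_coarse):
        s = solved_m1_coarse.solution.element_stress
        assert np.allclose(s, np.transpose(s, (0, 2, 1)), atol=1e-10 * np.abs(s).max())


class TestIncrementation:
    def test_settings_validated(self):
        with pytest.raises(ValueError):
            SolverSettings(initial_increment=2.0)
        with pytest.raises(ValueError):
            SolverSettings(min_increment=0.5, initial_increment=0.1)

    def test_failure_is_diagnostic(self, model1, mesh_m1_coarse):
        """An impossible load reports the increment collapse, not a crash."""
        load = apply_load(mesh_m1_coarse, LoadCase(pressure=1e6))
        with pytest.raises(SolveError, match="increment"):
            solve(
                mesh_m1_coarse,
                model1,
                load=load,
                settings=SolverSettings(min_increment=1e-3, max_increments=50, newton_max_iter=8),
            )

    def test_boundary_edges_closed_loop(self, mesh_m1_coarse):
        """Every exterior edge is used exactly once; counts match perimeter."""
        edges = boundary_edges(mesh_m1_coarse)
        ends = np.concatenate([edges[:, 0], edges[:, 2]])
        _, counts = np.unique(ends, return_counts=True)
        assert np.all(counts == 2)  # each corner node links two edges


class TestRigidPunch:
    def test_reaction_matches_target(self, model1, mesh_m1_coarse):
        p = 6.0
        sol = solve_rigid_punch(mesh_m1_coarse, model1, p)
        r, z = mesh_m1_coarse.nodes[:, 0], mesh_m1_coarse.nodes[:, 1]
        pn = np.nonzero((np.abs(z) < 1e-9) & (r <= 5.0 + 1e-9))[0]
        reac = sol.internal_force[2 * pn + 1].sum()
        assert reac == pytest.approx(p * np.pi * 25.0, rel=2e-3)
        # frictionless: punch nodes share one vertical displacement
        uz = sol.displacement[pn, 1]
        assert np.ptp(uz) < 1e-9 * max(1.0, np.abs(uz).max())
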