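"""Finite-strain solver verification against analytic and FD oracles."""

import numpy as np
import pytest
from scipy.optimize import brentq

from cellscale.fe_solver import (
    BoundaryConditionSet,
    SolverSettings,
    apply_boundary_conditions,
    boundary_nodes,
    cauchy_stress,
    solve_static,
    strain_energy_density,
    uniform_micro_model,
)
from cellscale.mesh import structured_hex_grid
from cellscale.microgen import (
    Material,
    assign_materials,
    build_micro_mesh,
    default_material_table,
    place_chondrons,
)

ECM = Material(1.6892, 0.0, 83.3333)
PCM = Material(0.6838, 0.0, 1.0570)
CELL = Material(0.0405, 0.0, 1.9980)


class TestBoundaryConditions:
    def test_identity_gives_zero_displacement(self):
        mesh = structured_hex_grid((3, 3, 3), (100.0,) * 3)
        bcs = apply_boundary_conditions(mesh, np.eye(3))
        assert np.allclose(bcs.displacements, 0.0)

    def test_corner_arithmetic(self):
        mesh = structured_hex_grid((2, 2, 2), (100.0,) * 3)
        bcs = apply_boundary_conditions(mesh, np.diag([0.9, 1.0, 1.0]))
        corner = np.flatnonzero(
            (np.abs(mesh.nodes - [100.0, 0.0, 0.0]) < 1e-9).all(axis=1)
        )[0]
        row = np.flatnonzero(bcs.node_ids == corner)[0]
        assert np.allclose(bcs.displacements[row], [-10.0, 0.0, 0.0])

    def test_shear_matches_formula_on_face_nodes(self, rng):
        mesh = structured_hex_grid((4, 4, 4), (100.0,) * 3)
        F = np.eye(3)
        F[0, 1] = 0.1
        bcs = apply_boundary_conditions(mesh, F)
        pick = rng.choice(len(bcs.node_ids), size=50, replace=False)
        X = mesh.nodes[bcs.node_ids[pick]]
        assert np.allclose(bcs.displacements[pick], X @ (F - np.eye(3)).T,
                           atol=1e-12)

    def test_every_face_node_present_once_interior_absent(self):
        mesh = structured_hex_grid((3, 3, 3), (1.0,) * 3)
        bcs = apply_boundary_conditions(mesh, np.diag([1.1, 1.0, 1.0]))
        faces = boundary_nodes(mesh)
        assert sorted(bcs.node_ids) == sorted(faces)
        assert len(set(bcs.node_ids)) == len(bcs.node_ids)

    def test_nonpositive_det_rejected(self):
        mesh = structured_hex_grid((2, 2, 2), (1.0,) * 3)
        with pytest.raises(ValueError):
            apply_boundary_conditions(mesh, np.diag([-1.0, 1.0, 1.0]))


class TestCauchyStress:
    def test_zero_at_identity(self):
        assert np.allclose(cauchy_stress(np.eye(3), ECM), 0.0)

    def test_pure_dilation_is_hydrostatic(self):
        alpha = 1.05
        sig = cauchy_stress(alpha * np.eye(3), ECM)
        J = alpha**3
        p = ECM.K * np.log(J) / J
        assert np.allclose(sig, p * np.eye(3), atol=1e-12)
        dev = sig - np.trace(sig) / 3 * np.eye(3)
        assert np.abs(dev).max() < 1e-12

    @pytest.mark.parametrize("mat", [ECM, PCM, CELL,
                                     Material(1.2, 0.4, 20.0)])
    def test_matches_energy_differentiation(self, mat, rng):
        for _ in range(3):
            F = np.eye(3) + 0.15 * rng.standard_normal((3, 3))
            if np.linalg.det(F) < 0.4:
                continue
            h = 1e-6
            P = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    P[i, j] = (
                        strain_energy_density(Fp, mat)
                        - strain_energy_density(Fm, mat)
                    ) / (2 * h)
            sig_fd = P @ F.T / np.linalg.det(F)
            sig = cauchy_stress(F, mat)
            scale = max(np.abs(sig).max(), 1.0)
            assert np.abs(sig - sig_fd).max() / scale < 1e-6
            assert np.allclose(sig, sig.T)

    def test_inverted_state_rejected(self):
        with pytest.raises(ValueError):
            cauchy_stress(np.diag([-1.0, 1.0, 1.0]), ECM)


def _incompressible_axial(lam, c1, c2=0.0):
    return 2.0 * (c1 + c2 / lam) * (lam**2 - 1.0 / lam)


def _compressible_axial(lam, mat):
    """Semi-analytic uniaxial solution: root-find the lateral stretch."""

    def sig(lamT):
        F = np.diag([lamT, lamT, lam])
        return cauchy_stress(F, mat)

    lamT = brentq(lambda t: sig(t)[0, 0], 0.3, 3.0, xtol=1e-14)
    return sig(lamT)[2, 2]


def _uniaxial_bcs(mesh, lam):
    """Prescribed z-faces, free lateral faces, rigid modes pinned."""
    lo, hi = mesh.nodes.min(axis=0), mesh.nodes.max(axis=0)
    z = mesh.nodes[:, 2]
    tol = 1e-9 * max(hi[2] - lo[2], 1.0)
    ids = np.flatnonzero((np.abs(z - lo[2]) < tol) | (np.abs(z - hi[2]) < tol))
    disp = np.full((len(ids), 3), np.nan)
    disp[:, 2] = (lam - 1.0) * (mesh.nodes[ids, 2] - lo[2])
    c0 = int(np.argmin(np.linalg.norm(mesh.nodes - lo, axis=1)))
    c1n = int(np.argmin(np.linalg.norm(mesh.nodes - [hi[0], lo[1], lo[2]], axis=1)))
    for nid, comps in ((c0, (0, 1)), (c1n, (1,))):
        row = np.flatnonzero(ids == nid)[0]
        disp[row, list(comps)] = 0.0
    return BoundaryConditionSet(ids, disp)


class TestSolveStatic:
    @pytest.mark.parametrize("mat", [ECM, PCM, CELL])
    def test_patch_test_per_material(self, mat):
        """Affine BCs on a homogeneous block reproduce the affine field."""
        mesh = structured_hex_grid((3, 3, 3), (100.0,) * 3)
        model = uniform_micro_model(mesh, mat)
        F0 = np.array([[0.96, 0.04, 0.0], [0.0, 1.03, 0.02], [0.01, 0.0, 0.93]])
        sol = solve_static(model, apply_boundary_conditions(mesh, F0),
                           SolverSettings(n_steps=1, tol=1e-12))
        assert sol.converged
        u_exact = mesh.nodes @ (F0 - np.eye(3)).T
        scale = np.abs(u_exact).max()
        assert np.abs(sol.displacement - u_exact).max() / scale < 1e-8
        sig = sol.cauchy
        assert np.abs(sig - cauchy_stress(F0, mat)).max() < 1e-8

    @pytest.mark.parametrize("lam", [0.8, 1.2])
    def test_uniaxial_matches_semianalytic_compressible(self, lam):
        mesh = structured_hex_grid((3, 3, 3), (1.0,) * 3)
        model = uniform_micro_model(mesh, ECM)
        sol = solve_static(model, _uniaxial_bcs(mesh, lam),
                           SolverSettings(n_steps=4))
        assert sol.converged
        s_fe = sol.cauchy[:, 2, 2].mean()
        s_exact = _compressible_axial(lam, ECM)
        assert abs(s_fe / s_exact - 1.0) < 5e-3

    def test_uniaxial_approaches_incompressible_limit(self):
        lam = 1.2
        errs = []
        for K in (83.3333, 1e3, 1e4):
            mat = Material(ECM.c1, 0.0, K)
            mesh = structured_hex_grid((3, 3, 3), (1.0,) * 3)
            model = uniform_micro_model(mesh, mat)
            sol = solve_static(model, _uniaxial_bcs(mesh, lam),
                               SolverSettings(n_steps=4))
            assert sol.converged
            s_fe = sol.cauchy[:, 2, 2].mean()
            errs.append(abs(s_fe / _incompressible_axial(lam, ECM.c1) - 1.0))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-3

    def test_residual_decreases_within_newton_sequence(self):
        mesh = structured_hex_grid((4, 4, 4), (100.0,) * 3)
        model = uniform_micro_model(mesh, ECM)
        F0 = np.diag([0.9**-0.5, 0.9**-0.5, 0.9])
        sol = solve_static(model, apply_boundary_conditions(mesh, F0),
                           SolverSettings(n_steps=2))
        assert sol.converged
        for step in sol.diagnostics["residual_history"]:
            res = step["residuals"]
            assert all(res[i + 1] < res[i] for i in range(len(res) - 1))

    def test_solution_invariant_under_node_renumbering(self, rng):
        mesh = structured_hex_grid((3, 3, 3), (100.0,) * 3)
        model = uniform_micro_model(mesh, ECM)
        F0 = np.diag([0.95, 1.02, 0.97])
        sol = solve_static(model, apply_boundary_conditions(mesh, F0),
                           SolverSettings(n_steps=1))
        perm = rng.permutation(mesh.n_nodes)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(mesh.n_nodes)
        mesh2 = structured_hex_grid((3, 3, 3), (100.0,) * 3)
        mesh2.nodes = mesh.nodes[perm]
        mesh2.elements = inv[mesh.elements]
        model2 = uniform_micro_model(mesh2, ECM)
        sol2 = solve_static(model2, apply_boundary_conditions(mesh2, F0),
                            SolverSettings(n_steps=1))
        assert np.abs(sol2.displacement[inv] - sol.displacement).max() < 1e-8

    def test_nonconvergence_is_contained_not_raised(self):
        # boundary displacement that reflects the block (det < 0 target):
        # unreachable through untangled configurations
        mesh = structured_hex_grid((3, 3, 3), (100.0,) * 3)
        model = uniform_micro_model(mesh, ECM)
        ids = boundary_nodes(mesh)
        disp = np.zeros((len(ids), 3))
        disp[:, 0] = -2.0 * mesh.nodes[ids, 0]
        bcs = BoundaryConditionSet(ids, disp)
        sol = solve_static(model, bcs,
                           SolverSettings(n_steps=1, max_iterations=4))
        assert sol.status == "failed"
        assert "reason" in sol.diagnostics

    def test_unconstrained_problem_raises(self):
        mesh = structured_hex_grid((2, 2, 2), (1.0,) * 3)
        model = uniform_micro_model(mesh, ECM)
        with pytest.raises(ValueError):
            solve_static(model, BoundaryConditionSet(np.array([], dtype=int),
                                                     np.zeros((0, 3))))

    def test_single_cell_strain_amplification(self):
        """The soft cell deforms more than the surrounding ECM."""
        from cellscale.metrics import effective_scalar, volume_averaged_metric

        model = assign_materials(build_micro_mesh(place_chondrons(1), 16),
                                 default_material_table())
        F = np.diag([0.95**-0.5, 0.95**-0.5, 0.95])
        sol = solve_static(model, apply_boundary_conditions(model.mesh, F),
                           SolverSettings(n_steps=1))
        assert sol.converged
        eff = effective_scalar(sol.green_strain)
        cell = volume_averaged_metric(sol, "Cell", eff)
        ecm = volume_averaged_metric(sol, "ECM", eff)
        assert cell > ecm
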