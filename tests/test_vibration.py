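"""Fold-mesh, operator-assembly and time-stepping tests."""

import numpy as np
import pytest
import scipy.linalg

from larynxsim.config import DEFAULT_CONFIG
from larynxsim.posture import apply_posture_rules
from larynxsim.tissue import TissueState
from larynxsim.vibration import (DegenerateGeometryError, VibrationState,
                                 assemble_system, build_mesh,
                                 mechanical_energy, static_deflection, step)

GEOM = apply_posture_rules(0.0, 0.2, 0.04)


def make_tissue(sigma=2e4, mu=None, eta=None):
    cfg = DEFAULT_CONFIG
    t = TissueState.zeros(mu=mu if mu is not None else cfg.mu_gel,
                          eta=eta if eta is not None else cfg.eta_gel)
    for k in t.sigma_fiber:
        t.sigma_fiber[k] = sigma
        t.sigma_y[k] = sigma
        t.mu_prime[k] = max(0.0, sigma)
    return t


@pytest.fixture(scope="module")
def mesh():
    return build_mesh(GEOM)


@pytest.fixture(scope="module")
def ops(mesh):
    return assemble_system(mesh, make_tissue())


class TestMesh:
    def test_counts(self, mesh):
        assert mesh.n_slices == 15
        assert mesh.nodes_per_slice == 77
        assert mesh.elements_per_slice == 120

    def test_medial_column_lies_on_half_width_field(self, mesh):
        assert np.allclose(mesh.X[:, :, 0], mesh.xi0)

    def test_posterior_end_slice_on_midline(self, mesh):
        assert np.allclose(mesh.xi0[-1], 0.0)

    def test_boundary_flags(self, mesh):
        assert mesh.fixed[:, :, -1].all()      # lateral
        assert mesh.fixed[0].all() and mesh.fixed[-1].all()  # ant/post
        assert not mesh.fixed[1:-1, :, 0].any()  # medial free
        assert not mesh.fixed[1:-1, 0, :-1].any()  # inferior free

    def test_curved_lateral_boundary(self, mesh):
        lat = mesh.X[7, :, -1]
        assert len(np.unique(np.round(lat, 10))) > 2

    def test_degenerate_geometry_rejected(self):
        bad = apply_posture_rules(0.0, 0.2, 0.04)
        object.__setattr__(bad, "T", -0.1)
        with pytest.raises(DegenerateGeometryError):
            build_mesh(bad)

    def test_left_fold_is_mirror(self, mesh):
        left = build_mesh(GEOM, side="left")
        assert np.allclose(left.X, -mesh.X)

    def test_json_export_round_trips_counts(self, mesh, tmp_path):
        import json
        path = tmp_path / "mesh.json"
        mesh.to_json(path)
        doc = json.loads(path.read_text())
        assert doc["n_slices"] == 15
        assert doc["nodes_per_slice"] == 77
        assert doc["elements_per_slice"] == 120
        assert np.allclose(doc["x_cm"], mesh.X)


class TestAssembly:
    def test_rest_state_is_equilibrium(self, ops, mesh):
        # zero displacement, zero load: zero net nodal force
        assert np.allclose(ops.K @ np.zeros(mesh.n_dof), 0.0)

    def test_stiffness_symmetric_positive_semidefinite(self, ops):
        K = ops.K.toarray()
        assert np.allclose(K, K.T, atol=1e-6 * np.abs(K).max())
        idx = np.where(ops.free)[0]
        w = np.linalg.eigvalsh(K[np.ix_(idx, idx)])
        assert w.min() > -1e-6 * w.max()

    def test_zero_fiber_stress_decouples_slices(self, mesh):
        ops0 = assemble_system(mesh, make_tissue(sigma=0.0))
        n = mesh.nodes_per_slice
        # force on a mid-slice node produces no response in other slices
        F = np.zeros(mesh.n_dof)
        F[mesh.dof(7, 3, 0, 0)] = 100.0
        u = static_deflection(ops0, F)
        u_slices = u.reshape(mesh.n_slices, 2 * n)
        moved = np.abs(u_slices).max(axis=1)
        assert moved[7] > 0
        assert np.allclose(moved[[1, 2, 3, 4, 5, 6, 8, 9, 10, 11, 12, 13]], 0,
                           atol=1e-14)
        assert moved[0] == 0 and moved[14] == 0

    def test_doubling_mu_scales_modal_frequencies_by_sqrt2(self, mesh):
        """Single clamped slice eigenvalue oracle: K linear in mu -> f ~ sqrt(mu)."""
        ops1 = assemble_system(mesh, make_tissue(sigma=0.0, mu=5e3))
        ops2 = assemble_system(mesh, make_tissue(sigma=0.0, mu=1e4))
        n = mesh.nodes_per_slice
        s = 7
        dofs = np.arange(2 * s * n, 2 * (s + 1) * n)
        free = ops1.free[dofs]
        idx = dofs[free]
        K1 = ops1.K[np.ix_(idx, idx)].toarray()
        K2 = ops2.K[np.ix_(idx, idx)].toarray()
        M = np.diag(ops1.M[idx])
        w1 = np.sort(scipy.linalg.eigh(K1, M, eigvals_only=True))
        w2 = np.sort(scipy.linalg.eigh(K2, M, eigvals_only=True))
        assert np.allclose(np.sqrt(w2[:20] / w1[:20]), np.sqrt(2.0), rtol=1e-9)


class TestStepping:
    def test_undamped_free_vibration_conserves_energy(self, mesh):
        """eta = 0: the symplectic scheme's staggered discrete energy
        E = v'Mv/2 + u_n'K u_{n+1}/2 is conserved over 1000 steps, and the
        collocated energy stays within a bounded band (no drift)."""
        ops = assemble_system(mesh, make_tissue(sigma=2e4, eta=0.0))
        ops.factorize(DEFAULT_CONFIG.dt)
        rng = np.random.default_rng(0)
        u = np.zeros(mesh.n_dof)
        u[ops.free] = 1e-4 * rng.standard_normal(int(ops.free.sum()))
        state = VibrationState(u=u, v=np.zeros(mesh.n_dof))
        F = np.zeros(mesh.n_dof)
        e0 = mechanical_energy(ops, state)
        staggered = []
        collocated = []
        for _ in range(1000):
            u_prev = state.u
            state = step(ops, state, F)
            staggered.append(0.5 * state.v @ (ops.M * state.v)
                             + 0.5 * u_prev @ (ops.K @ state.u))
            collocated.append(mechanical_energy(ops, state))
        staggered = np.asarray(staggered)
        # exact discrete invariant: far tighter than 1% over 10^3 steps
        assert np.all(np.abs(staggered - staggered[0]) < 1e-9 * e0)
        # collocated energy oscillates in a bounded band around it (no drift)
        assert (max(collocated) - min(collocated)) / e0 < 0.3

    def test_damped_free_vibration_dissipates(self, ops, mesh):
        ops.factorize(DEFAULT_CONFIG.dt)
        rng = np.random.default_rng(1)
        u = np.zeros(mesh.n_dof)
        u[ops.free] = 1e-4 * rng.standard_normal(int(ops.free.sum()))
        state = VibrationState(u=u, v=np.zeros(mesh.n_dof))
        F = np.zeros(mesh.n_dof)
        e0 = mechanical_energy(ops, state)
        for _ in range(2000):
            state = step(ops, state, F)
        e1 = mechanical_energy(ops, state)
        assert e1 < 0.5 * e0

    def test_no_energy_creation_without_lung_pressure(self, ops, mesh):
        """With no external forcing, energy is non-increasing at every step
        (up to the symplectic scheme's bounded oscillation)."""
        ops.factorize(DEFAULT_CONFIG.dt)
        rng = np.random.default_rng(2)
        v = np.zeros(mesh.n_dof)
        v[ops.free] = 1e-3 * rng.standard_normal(int(ops.free.sum()))
        state = VibrationState(u=np.zeros(mesh.n_dof), v=v)
        F = np.zeros(mesh.n_dof)
        prev = mechanical_energy(ops, state)
        for _ in range(500):
            state = step(ops, state, F)
            e = mechanical_energy(ops, state)
            assert e <= prev * 1.001
            prev = e

    def test_constant_load_converges_to_static_solution(self, mesh):
        """Sub-threshold constant pressure: long-time state matches the
        direct static solve."""
        ops = assemble_system(mesh, make_tissue())
        ops.factorize(DEFAULT_CONFIG.dt)
        F = np.zeros(mesh.n_dof)
        for s in range(1, 14):
            for j in range(7):
                F[mesh.dof(s, j, 0, 0)] = 50.0
        u_static = static_deflection(ops, F)
        state = VibrationState(u=np.zeros(mesh.n_dof), v=np.zeros(mesh.n_dof))
        for _ in range(6000):
            state = step(ops, state, F)
        err = np.abs(state.u - u_static).max()
        assert err < 0.02 * np.abs(u_static).max()

    def test_fixed_nodes_never_move(self, ops, mesh):
        ops.factorize(DEFAULT_CONFIG.dt)
        rng = np.random.default_rng(3)
        F = rng.standard_normal(mesh.n_dof) * 10
        state = VibrationState(u=np.zeros(mesh.n_dof), v=np.zeros(mesh.n_dof))
        for _ in range(100):
            state = step(ops, state, F)
        assert np.all(state.u[~ops.free] == 0.0)


class TestSymmetry:
    def test_left_right_mirror_dynamics(self):
        """A mirrored left fold under mirrored loads reproduces the right
        fold's motion with the lateral displacement negated."""
        rng = np.random.default_rng(7)
        for trial in range(10):
            right = build_mesh(GEOM, side="right")
            left = build_mesh(GEOM, side="left")
            tr = make_tissue()
            ops_r = assemble_system(right, tr)
            ops_l = assemble_system(left, tr)
            ops_r.factorize(DEFAULT_CONFIG.dt)
            ops_l.factorize(DEFAULT_CONFIG.dt)
            F = np.zeros(right.n_dof)
            F[ops_r.free] = rng.standard_normal(int(ops_r.free.sum()))
            F_mirror = F.copy()
            F_mirror[0::2] *= -1.0  # lateral components flip
            sr = VibrationState(u=np.zeros(right.n_dof), v=np.zeros(right.n_dof))
            sl = VibrationState(u=np.zeros(left.n_dof), v=np.zeros(left.n_dof))
            for _ in range(20):
                sr = step(ops_r, sr, F)
                sl = step(ops_l, sl, F_mirror)
            assert np.allclose(sl.u[0::2], -sr.u[0::2], atol=1e-14)
            assert np.allclose(sl.u[1::2], sr.u[1::2], atol=1e-14)
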