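"""Online stage: parametric coordinate estimation, local bases, manifold
learning, low-order integration."""

import numpy as np
import pytest

from capsrom.diffuse import DAConfig
from capsrom.offline import GlobalBases, OfflineConfig, run_offline
from capsrom.online import (
    Manifold,
    OnlineConfig,
    QueryModel,
    build_query_model,
    coupling_matrix,
    estimate_parametric_coordinates,
    local_pod,
    manifold_eval,
    manifold_fit,
    project_reduced_data,
    pseudo_snapshots,
    reconstruct_fields,
    rom_integrate,
    run_online,
)
from capsrom.params import DesignOfExperiment, ParameterPoint, build_doe


def synthetic_bases(nc=40, k=3, seed=0):
    """Global bases whose parametric mode rows are exact quadratics of
    theta, for reproduction checks."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform([0.01, 0.76], [0.19, 1.19], size=(nc, 2))
    coeffs = rng.normal(size=(k, 6))

    def psi_of(th):
        ca, b = th[..., 0], th[..., 1]
        mono = np.stack(
            [np.ones_like(ca), ca, b, ca * b, ca**2, b**2], axis=-1
        )
        return mono @ coeffs.T

    psi = psi_of(pts)  # (nc, k)
    nt, n3 = 4, 9
    phi = np.linalg.qr(rng.normal(size=(n3, k)))[0]
    A = rng.normal(size=(nt, k, k))
    times = 0.2 * np.arange(1, nt + 1)
    bases = GlobalBases(
        phi_u=phi, phi_v=phi, psi_u=psi, psi_v=psi,
        sing_S_u=np.ones(k), sing_S_v=np.ones(k),
        sing_T_u=np.ones(k), sing_T_v=np.ones(k),
        A=A, B=A, times=times, doe_points=pts,
    )
    return bases, psi_of


class TestParametricEstimation:
    def test_quadratic_reproduction(self):
        """Rows of Psi that are exact quadratics of theta are recovered
        exactly by second-order DA."""
        bases, psi_of = synthetic_bases()
        cfg = DAConfig(order=2, neighbor_count=12, ridge=0.0)
        rng = np.random.default_rng(1)
        for _ in range(20):
            q = rng.uniform([0.03, 0.8], [0.17, 1.15], size=2)
            theta = ParameterPoint(*q)
            psi_u, psi_v = estimate_parametric_coordinates(theta, bases, cfg)
            assert np.allclose(psi_u, psi_of(q), atol=1e-9)
            assert np.allclose(psi_v, psi_of(q), atol=1e-9)

    def test_output_lengths(self):
        bases, _ = synthetic_bases(k=3)
        psi_u, psi_v = estimate_parametric_coordinates(
            ParameterPoint(0.1, 0.9), bases, DAConfig()
        )
        assert psi_u.shape == (3,) and psi_v.shape == (3,)


class TestPseudoSnapshots:
    def test_zero_coordinates_give_zero_matrix(self):
        bases, _ = synthetic_bases()
        out = pseudo_snapshots(np.zeros(3), bases.A, bases.phi_u)
        assert out.shape == (9, 4)
        assert np.allclose(out, 0.0)

    def test_columns_match_definition(self):
        bases, _ = synthetic_bases()
        psi = np.array([0.5, -1.0, 2.0])
        out = pseudo_snapshots(psi, bases.A, bases.phi_u)
        for i in range(4):
            assert np.allclose(out[:, i], bases.phi_u @ bases.A[i] @ psi)

    def test_exact_at_doe_sample_with_full_ranks(self):
        """At a design sample with exact psi and untruncated ranks the
        pseudo-snapshots equal the stored snapshots."""
        from capsrom.datacube import DataCube

        rng = np.random.default_rng(3)
        nc, nt, n3 = 5, 3, 12
        points = [ParameterPoint(0.02 + 0.03 * j, 0.8 + 0.05 * j) for j in range(nc)]
        cube = DataCube(
            u=rng.normal(size=(n3, nt, nc)),
            v=rng.normal(size=(n3, nt, nc)),
            times=0.2 * np.arange(1, nt + 1),
            doe=DesignOfExperiment(points=points),
        )
        bases = run_offline(cube, OfflineConfig(k_u_x=n3, k_u_c=nc, k_v_x=n3, k_v_c=nc))
        j = 2
        out = pseudo_snapshots(bases.psi_u[j], bases.A, bases.phi_u)
        assert np.allclose(out, cube.u[:, :, j], atol=1e-8)


class TestLocalBasisAndProjection:
    def test_rank_two_capture(self):
        rng = np.random.default_rng(4)
        M = np.outer(rng.normal(size=30), rng.normal(size=8))
        M += np.outer(rng.normal(size=30), rng.normal(size=8))
        basis, _ = local_pod(M, m=2)
        resid = M - basis @ (basis.T @ M)
        assert np.linalg.norm(resid) < 1e-10 * np.linalg.norm(M)

    def test_rank_clamp_warns(self):
        M = np.outer(np.arange(1.0, 5.0), np.ones(3))
        with pytest.warns(UserWarning, match="clamp"):
            basis, _ = local_pod(M, m=5)
        assert basis.shape == (4, 3)

    def test_coupling_matrix_cases(self):
        rng = np.random.default_rng(5)
        Q_full = np.linalg.qr(rng.normal(size=(10, 6)))[0]
        phi, gamma = Q_full[:, :3], Q_full[:, 3:]
        assert np.allclose(coupling_matrix(phi, phi), np.eye(3), atol=1e-12)
        assert np.allclose(coupling_matrix(phi, gamma), 0.0, atol=1e-12)
        # random orthonormal factors: spectral norm <= 1
        A = np.linalg.qr(rng.normal(size=(20, 4)))[0]
        B = np.linalg.qr(rng.normal(size=(20, 5)))[0]
        assert np.linalg.norm(coupling_matrix(A, B), 2) <= 1 + 1e-10

    def test_projection_optimality(self):
        """No perturbed coefficient vector beats the orthogonal projection
        residual (convexity probe)."""
        rng = np.random.default_rng(6)
        basis = np.linalg.qr(rng.normal(size=(15, 4)))[0]
        x = rng.normal(size=(15, 1))
        alpha = project_reduced_data(x, basis)
        best = np.linalg.norm(x - basis @ alpha)
        for _ in range(30):
            pert = alpha + rng.normal(scale=1e-3, size=alpha.shape)
            assert np.linalg.norm(x - basis @ pert) >= best - 1e-15

    def test_projection_unit_cases(self):
        rng = np.random.default_rng(7)
        basis = np.linalg.qr(rng.normal(size=(12, 3)))[0]
        alpha = project_reduced_data(basis[:, [1]], basis)
        assert np.allclose(alpha.ravel(), [0, 1, 0], atol=1e-12)

    def test_reconstruct_fields(self):
        rng = np.random.default_rng(8)
        basis = np.linalg.qr(rng.normal(size=(12, 3)))[0]
        assert np.allclose(reconstruct_fields(np.eye(3)[:, 1], basis), basis[:, 1])
        assert np.allclose(reconstruct_fields(np.zeros(3), basis), 0.0)
        x = rng.normal(size=12)
        proj = reconstruct_fields(project_reduced_data(x, basis), basis)
        proj2 = reconstruct_fields(project_reduced_data(proj, basis), basis)
        assert np.allclose(proj, proj2, atol=1e-12)


class TestManifold:
    def test_constant_data(self):
        times = 0.2 * np.arange(1, 11)
        alpha = np.random.default_rng(9).normal(size=(3, 10))
        xi = 2.5 * np.ones((2, 10))
        A = manifold_fit(alpha, xi, times, 1.0, window=0.4)
        assert A.shape == (2, 4)
        assert np.allclose(A[:, 0], 2.5, atol=1e-9)
        assert np.allclose(A[:, 1:], 0.0, atol=1e-9)

    def test_linear_embedding_reproduction(self):
        rng = np.random.default_rng(10)
        times = 0.2 * np.arange(1, 31)
        alpha = rng.normal(size=(4, 30))
        L = rng.normal(size=(3, 4))
        xi = L @ alpha
        manifold = Manifold(alpha, xi, times, window=0.4)
        for i in (0, 7, 15, 29):
            pred = manifold_eval(alpha[:, i], times[i], manifold)
            assert np.allclose(pred, xi[:, i], atol=1e-8)

    def test_intercepts_at_zero_alpha(self):
        times = 0.2 * np.arange(1, 11)
        alpha = np.zeros((2, 10))
        xi = np.vstack([times, 2 * times])
        manifold = Manifold(alpha, xi, times, window=0.4)
        out = manifold.eval(np.zeros(2), 1.0)
        assert out.shape == (2,)
        assert out == pytest.approx([1.0, 2.0], abs=1e-9)


class TestIntegration:
    def make_query_model(self, mu, mv, Q):
        n3 = max(mu, mv) + 2
        rng = np.random.default_rng(11)
        basis = np.linalg.qr(rng.normal(size=(n3, mu + mv)))[0]
        return QueryModel(
            theta_q=ParameterPoint(0.1, 0.9),
            psi_u=np.zeros(1), psi_v=np.zeros(1),
            U_q=np.zeros((n3, 4)), V_q=np.zeros((n3, 4)),
            phi_q=basis[:, :mu], gamma_q=basis[:, mu : mu + mv],
            Q=Q,
            alpha_D=np.zeros((mu, 4)), xi_D=np.zeros((mv, 4)),
            times=0.2 * np.arange(1, 5),
        )

    def test_constant_xi_telescopes_exactly(self):
        """xi = c with Q = I integrates to alpha_n = n dt c exactly."""
        mu = mv = 3
        c = np.array([1.0, -2.0, 0.5])
        times = 0.2 * np.arange(1, 11)
        manifold = Manifold(
            alpha_D=np.zeros((mu, 10)),
            xi_D=np.tile(c[:, None], (1, 10)),
            times=times,
            window=0.4,
        )
        qm = self.make_query_model(mu, mv, np.eye(3))
        traj = rom_integrate(qm, manifold, dt_rom=0.1, t_final=1.0)
        for n in range(11):
            assert np.allclose(traj.alpha[:, n], n * 0.1 * c, atol=1e-9)

    def test_scalar_linear_decay_matches_closed_form(self):
        """xi = -alpha gives the geometric recursion
        alpha^{n+1} = (1 - dt) alpha^n + dt*offset behaviour."""
        times = 0.2 * np.arange(1, 21)
        # data: xi = 1 - alpha along a trajectory rich enough to identify it
        alpha_D = np.linspace(0.0, 0.9, 20)[None, :]
        xi_D = 1.0 - alpha_D
        manifold = Manifold(alpha_D, xi_D, times, window=100.0)
        qm = self.make_query_model(1, 1, np.eye(1))
        dt = 0.1
        traj = rom_integrate(qm, manifold, dt_rom=dt, t_final=2.0)
        expected = 1.0 - (1.0 - dt) ** np.arange(21)
        assert np.allclose(traj.alpha[0], expected, atol=1e-8)

    def test_nonfinite_state_aborts_with_step(self):
        times = 0.2 * np.arange(1, 5)
        manifold = Manifold(
            alpha_D=np.zeros((1, 4)),
            xi_D=np.full((1, 4), 1e308),
            times=times,
            window=100.0,
        )
        qm = self.make_query_model(1, 1, np.eye(1))
        with pytest.raises(FloatingPointError, match="step"):
            rom_integrate(qm, manifold, dt_rom=1e3, t_final=4e3)

    def test_bad_dt_rejected(self):
        qm = self.make_query_model(1, 1, np.eye(1))
        manifold = Manifold(np.zeros((1, 4)), np.zeros((1, 4)), 0.2 * np.arange(1, 5), 0.4)
        with pytest.raises(ValueError):
            rom_integrate(qm, manifold, dt_rom=-0.1, t_final=1.0)


@pytest.fixture(scope="module")
def small_problem():
    import capsrom as cr

    mesh = cr.subdivide_icosphere(2)
    doe = build_doe(ca_step=0.025, beta_step=0.15, extra_ca=(0.005,))
    cube = cr.build_database(doe, mesh, dt=0.25, T=5.0)
    bases = run_offline(cube, OfflineConfig(k_u_x=10, k_u_c=10, k_v_x=10, k_v_c=10))
    return mesh, cube, bases


class TestEndToEnd:
    def test_repeat_runs_bit_identical(self, small_problem):
        _, _, bases = small_problem
        theta = ParameterPoint(0.06, 0.9)
        cfg = OnlineConfig(mu=5, mv=5)
        _, t1 = run_online(theta, bases, cfg)
        _, t2 = run_online(theta, bases, cfg)
        assert np.array_equal(t1.alpha, t2.alpha)
        assert np.array_equal(t1.xi, t2.xi)

    def test_local_bases_orthonormal_and_coupling_contractive(self, small_problem):
        _, _, bases = small_problem
        qm = build_query_model(ParameterPoint(0.06, 0.9), bases, OnlineConfig(mu=5, mv=5))
        assert np.allclose(qm.phi_q.T @ qm.phi_q, np.eye(qm.phi_q.shape[1]), atol=1e-10)
        assert np.allclose(qm.gamma_q.T @ qm.gamma_q, np.eye(qm.gamma_q.shape[1]), atol=1e-10)
        assert np.linalg.norm(qm.Q, 2) <= 1 + 1e-10

    def test_manifold_consistency_at_snapshot_times(self, small_problem):
        """At snapshot times the manifold evaluated on the projected data
        approximately returns the projected velocity coordinates."""
        _, _, bases = small_problem
        cfg = OnlineConfig(mu=5, mv=5)
        qm = build_query_model(ParameterPoint(0.06, 0.9), bases, cfg)
        manifold = Manifold(qm.alpha_D, qm.xi_D, qm.times, window=0.5)
        scale = np.abs(qm.xi_D).max()
        for i in (2, 6, 12):
            pred = manifold.eval(qm.alpha_D[:, i], qm.times[i])
            assert np.allclose(pred, qm.xi_D[:, i], atol=5e-3 * scale)

    def test_rigid_translation_recovered_to_integration_accuracy(self):
        """Pure rigid translation (zero deformation gains): the ROM
        reproduces the node positions exactly when xi is constant and
        dt_rom equals the snapshot step."""
        import capsrom as cr
        from capsrom.surrogate import SurrogateParams, centerline_speed

        mesh = cr.subdivide_icosphere(1)
        doe = build_doe(ca_step=0.05, beta_step=0.15, extra_ca=(0.005,))
        params = SurrogateParams(q0=0.0, parachute_gain=0.0)
        cube = cr.build_database(doe, mesh, dt=0.25, T=5.0, params=params)
        bases = run_offline(cube, OfflineConfig(k_u_x=2, k_u_c=2, k_v_x=2, k_v_c=2))
        theta = ParameterPoint(0.07, 0.9)
        qm, traj = run_online(theta, bases, OnlineConfig(mu=1, mv=1, dt_rom=0.25))
        u_rom = qm.phi_q @ traj.alpha
        uc = centerline_speed()
        for n, t in enumerate(traj.times):
            expected = np.zeros(3 * mesh.n_vertices)
            expected[2::3] = uc * t
            assert np.allclose(u_rom[:, n], expected, atol=1e-6 * max(t, 1.0))

    def test_reduced_energy_stays_bounded(self, small_problem):
        """Stability guard: |alpha|^2 stays below a hard ceiling set by the
        data amplitude (no blow-up over the integration horizon)."""
        _, cube, bases = small_problem
        theta = ParameterPoint(0.06, 0.9)
        qm, traj = run_online(theta, bases, OnlineConfig(mu=5, mv=5))
        ceiling = 10.0 * np.max(np.sum(qm.alpha_D**2, axis=0))
        assert np.all(np.sum(traj.alpha**2, axis=0) <= ceiling)
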