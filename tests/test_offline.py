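"""Offline stage: SVD truncation, information content, coefficient
matrices, clustering."""

import numpy as np
import pytest

from capsrom.datacube import DataCube
from capsrom.offline import (
    ClusterPartition,
    OfflineConfig,
    assign_cluster,
    coefficient_matrices,
    decay_ratio,
    load_bases,
    rank_for_tolerance,
    relative_information_content,
    run_offline,
    save_bases,
    truncated_svd,
)
from capsrom.params import DesignOfExperiment, ParameterPoint


class TestTruncatedSVD:
    def test_diagonal_matrix(self):
        U, s, V = truncated_svd(np.diag([3.0, 2.0, 1.0]))
        assert np.allclose(s, [3, 2, 1])
        assert np.allclose(np.abs(U), np.eye(3), atol=1e-14)
        assert np.allclose(U, V, atol=1e-14)  # canonical signs make them equal

    def test_rank_one_outer_product(self):
        a = np.array([1.0, -2.0, 2.0])
        b = np.array([3.0, 4.0])
        U, s, V = truncated_svd(np.outer(a, b), rank=1)
        assert s[0] == pytest.approx(np.linalg.norm(a) * np.linalg.norm(b))
        assert np.allclose(s[1:], 0.0, atol=1e-12)

    def test_eckart_young(self):
        """Truncation residual^2 equals the tail energy sum (oracle:
        directly computed residual for every K)."""
        rng = np.random.default_rng(8)
        M = rng.normal(size=(30, 10))
        U, s, V = truncated_svd(M)
        for K in range(1, 11):
            resid = np.linalg.norm(M - U[:, :K] * s[:K] @ V[:, :K].T) ** 2
            assert resid == pytest.approx(np.sum(s[K:] ** 2), abs=1e-8)

    def test_full_rank_reconstruction_and_orthonormality(self):
        rng = np.random.default_rng(9)
        M = rng.normal(size=(12, 7))
        U, s, V = truncated_svd(M)
        assert np.allclose(U.T @ U, np.eye(7), atol=1e-10)
        assert np.allclose(V.T @ V, np.eye(7), atol=1e-10)
        assert np.allclose(U * s @ V.T, M, atol=1e-10)

    def test_rank_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            U, s, V = truncated_svd(np.eye(3), rank=5)
        assert U.shape == (3, 3)

    def test_sign_canonicalization_row_permutation(self):
        """Permuting input rows permutes left modes but leaves signs and
        right modes identical."""
        rng = np.random.default_rng(10)
        M = rng.normal(size=(20, 6))
        perm = rng.permutation(20)
        U1, s1, V1 = truncated_svd(M)
        U2, s2, V2 = truncated_svd(M[perm])
        assert np.allclose(s1, s2)
        assert np.allclose(U1[perm], U2, atol=1e-9)
        assert np.allclose(V1, V2, atol=1e-9)


class TestInformationContent:
    def test_full_rank_captures_everything(self):
        s = np.array([5.0, 1.0, 0.5])
        assert relative_information_content(s, 3) == pytest.approx(1.0)

    def test_hand_value(self):
        assert relative_information_content(np.array([2.0, 1.0, 1.0]), 1) == (
            pytest.approx(4.0 / 6.0)
        )

    def test_monotone_in_K(self):
        rng = np.random.default_rng(11)
        s = np.sort(rng.uniform(0, 5, size=12))[::-1]
        rics = [relative_information_content(s, K) for K in range(13)]
        assert np.all(np.diff(rics) >= 0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            relative_information_content(np.zeros(3), 1)

    def test_decay_ratio(self):
        assert decay_ratio(np.array([4.0, 1.0]), 2) == pytest.approx(0.25)

    @pytest.mark.parametrize(
        "s,tol,expected",
        [([1.0, 1e-9], 1e-7, 1), ([1.0], 0.5, 1), ([2.0, 1.0, 0.5], 0.0, 3)],
    )
    def test_rank_for_tolerance(self, s, tol, expected):
        assert rank_for_tolerance(np.array(s), tol) == expected


def tiny_cube(nx=2, nt=2, nc=3, seed=0):
    rng = np.random.default_rng(seed)
    points = [ParameterPoint(0.02 * (j + 1), 0.8 + 0.05 * j) for j in range(nc)]
    return DataCube(
        u=rng.normal(size=(3 * nx, nt, nc)),
        v=rng.normal(size=(3 * nx, nt, nc)),
        times=0.2 * np.arange(1, nt + 1),
        doe=DesignOfExperiment(points=points),
    )


class TestOfflineStage:
    def test_full_rank_projection_identity(self):
        """Untruncated ranks reproduce every time slice of the cube."""
        cube = tiny_cube(nx=2, nt=3, nc=4, seed=1)
        cfg = OfflineConfig(k_u_x=6, k_u_c=4, k_v_x=6, k_v_c=4)
        bases = run_offline(cube, cfg)
        for i in range(cube.nt):
            rec = bases.phi_u @ bases.A[i] @ bases.psi_u.T
            assert np.allclose(rec, cube.u[:, i, :], atol=1e-8)
            rec_v = bases.phi_v @ bases.B[i] @ bases.psi_v.T
            assert np.allclose(rec_v, cube.v[:, i, :], atol=1e-8)

    def test_orthonormality_invariants(self):
        cube = tiny_cube(nx=4, nt=5, nc=6, seed=2)
        bases = run_offline(cube, OfflineConfig(k_u_x=5, k_u_c=4, k_v_x=5, k_v_c=4))
        for mat in (bases.phi_u, bases.phi_v, bases.psi_u, bases.psi_v):
            assert np.allclose(mat.T @ mat, np.eye(mat.shape[1]), atol=1e-10)
        assert np.all(np.diff(bases.sing_S_u) <= 1e-12)
        assert np.all(bases.sing_S_u >= 0)

    def test_rank_one_cube_coefficients(self):
        """A cube that is rank one in space and parameter yields a single
        dominant entry in A(t_i)."""
        cube = tiny_cube(nx=2, nt=2, nc=3, seed=3)
        space = np.arange(1.0, 7.0)
        conf = np.array([1.0, 2.0, 3.0])
        for i, scale in enumerate((1.0, 2.0)):
            cube.u[:, i, :] = scale * np.outer(space, conf)
        cube.v[:] = cube.u
        bases = run_offline(cube, OfflineConfig(k_u_x=2, k_u_c=2, k_v_x=2, k_v_c=2))
        for i in range(2):
            A = np.abs(bases.A[i])
            assert A[0, 0] == pytest.approx(np.max(A))
            assert np.sum(A > 1e-8 * A[0, 0]) == 1

    def test_coefficient_matrix_shapes(self):
        cube = tiny_cube(nx=3, nt=4, nc=5, seed=4)
        bases = run_offline(cube, OfflineConfig(k_u_x=3, k_u_c=2, k_v_x=4, k_v_c=3))
        assert bases.A.shape == (4, 3, 2)
        assert bases.B.shape == (4, 4, 3)

    def test_dimension_mismatch_rejected(self):
        cube = tiny_cube()
        bases = run_offline(cube, OfflineConfig(k_u_x=2, k_u_c=2, k_v_x=2, k_v_c=2))
        with pytest.raises(ValueError):
            coefficient_matrices(
                cube, bases.phi_u[:-1], bases.psi_u, bases.phi_v, bases.psi_v
            )

    def test_reproducible(self):
        cube = tiny_cube(nx=3, nt=3, nc=4, seed=5)
        cfg = OfflineConfig(k_u_x=3, k_u_c=3, k_v_x=3, k_v_c=3)
        b1 = run_offline(cube, cfg)
        b2 = run_offline(cube, cfg)
        assert np.array_equal(b1.phi_u, b2.phi_u)
        assert np.array_equal(b1.A, b2.A)

    def test_projection_error_equals_tail_energy(self):
        """Frobenius projection error of S onto its first K parametric
        modes equals sqrt(tail sum of squared singular values)."""
        from capsrom.datacube import stack_parametric

        cube = tiny_cube(nx=3, nt=4, nc=6, seed=6)
        S = stack_parametric(cube, "u").values
        U, s, V = truncated_svd(S)
        for K in (1, 3, 5):
            proj = S @ V[:, :K] @ V[:, :K].T
            err = np.linalg.norm(S - proj)
            assert err == pytest.approx(np.sqrt(np.sum(s[K:] ** 2)), abs=1e-8)

    def test_save_load_roundtrip(self, tmp_path):
        cube = tiny_cube(nx=3, nt=3, nc=4, seed=7)
        bases = run_offline(cube, OfflineConfig(k_u_x=3, k_u_c=3, k_v_x=3, k_v_c=3))
        save_bases(bases, tmp_path / "model")
        back = load_bases(tmp_path / "model")
        assert np.array_equal(back.phi_u, bases.phi_u)
        assert np.array_equal(back.B, bases.B)
        assert np.array_equal(back.doe_points, bases.doe_points)


class TestClustering:
    def make_doe(self):
        points = [
            ParameterPoint(ca, b)
            for ca in (0.02, 0.05, 0.08, 0.10, 0.13, 0.16)
            for b in (0.8, 0.9)
        ]
        return DesignOfExperiment(points=points)

    def test_labels_cover_domain(self):
        part = ClusterPartition()
        labels = part.labels(self.make_doe())
        assert set(labels) <= {0, 1, 2}
        assert (labels == 1).any() and (labels == 2).any()

    def test_deep_interior_assignment(self):
        doe = self.make_doe()
        part = ClusterPartition()
        assert assign_cluster(ParameterPoint(0.02, 0.9), part, doe) == 1
        assert assign_cluster(ParameterPoint(0.18, 0.8), part, doe) == 2

    def test_overlap_nearest_centroid_and_tiebreak(self):
        doe = self.make_doe()
        part = ClusterPartition(ca_split=0.10, overlap=0.02)
        cid = assign_cluster(ParameterPoint(0.099, 0.9), part, doe)
        assert cid in (1, 2)
        single = ClusterPartition(n_clusters=1)
        assert assign_cluster(ParameterPoint(0.15, 1.1), single, doe) == 1

    def test_member_indices_include_overlap(self):
        doe = self.make_doe()
        part = ClusterPartition(ca_split=0.10, overlap=0.04)
        m1 = set(part.member_indices(doe, 1).tolist())
        m2 = set(part.member_indices(doe, 2).tolist())
        assert m1 | m2 == set(range(doe.n_points))
        assert m1 & m2  # weak overlap is non-empty
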