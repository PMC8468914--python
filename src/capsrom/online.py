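"""Online stage: local reduced model and low-order time integration at a
query parameter.

For a query pair ``theta_q = (Ca, a/l)`` the stage (i) interpolates the
parametric POD coordinates ``psi_u, psi_v`` by diffuse approximation over
the design samples, (ii) assembles pseudo-snapshot matrices
``U(theta_q)[:, i] = Phi_u A(t_i) psi_u`` (and ``V`` from ``B``),
(iii) extracts low-order local bases ``Phi_q, Gamma_q`` by SVD of the
pseudo-snapshots, (iv) learns the manifold ``xi = M(t, alpha)`` linking
displacement and velocity reduced coordinates by temporal diffuse
approximation with order-zero/one monomials in ``alpha``, and (v) integrates
the discrete dynamical system

``alpha^{i+1} = alpha^i + dt_rom * Q xi^i``,   ``Q = Phi_q^T Gamma_q``,
``xi^{i+1}   = p(alpha^{i+1})^T a_k(t_{i+1})``

starting from ``alpha^0 = 0`` and ``xi^0`` given by the manifold at
``t = 0``.  High-dimensional fields are recovered as ``u = Phi_q alpha``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .diffuse import DAConfig, fit_parameter_da, temporal_da_fit
from .offline import GlobalBases, truncated_svd
from .params import ParameterPoint

__all__ = [
    "OnlineConfig",
    "QueryModel",
    "ROMTrajectory",
    "Manifold",
    "estimate_parametric_coordinates",
    "pseudo_snapshots",
    "local_pod",
    "coupling_matrix",
    "project_reduced_data",
    "manifold_fit",
    "manifold_eval",
    "rom_integrate",
    "reconstruct_fields",
    "build_query_model",
    "run_online",
]


@dataclass(frozen=True)
class OnlineConfig:
    """Settings of the online stage.

    ``mu``/``mv`` are the local truncation ranks; ``local_tol`` switches to
    tolerance-driven local truncation.  ``dt_rom=None`` uses half the
    snapshot step; ``temporal_window=None`` uses twice the snapshot step;
    ``t_final=None`` integrates to the last snapshot time.
    """

    da: DAConfig = field(default_factory=DAConfig)
    mu: int = 10
    mv: int = 10
    local_tol: float | None = None
    dt_rom: float | None = None
    temporal_window: float | None = None
    t_final: float | None = None


def estimate_parametric_coordinates(
    theta_q: ParameterPoint,
    bases: GlobalBases,
    da_config: DAConfig = DAConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Diffuse-approximation estimate of ``psi_u(theta_q), psi_v(theta_q)``.

    Each row of the truncated parametric mode matrices is a sample of a
    smooth function of ``theta``; a local polynomial fit over the design
    samples evaluated at the query yields the coordinate vectors (lengths
    ``Kuc`` and ``Kvc``).
    """
    q = theta_q.as_array()
    model_u = fit_parameter_da(q, bases.doe_points, bases.psi_u, da_config)
    model_v = fit_parameter_da(q, bases.doe_points, bases.psi_v, da_config)
    return model_u(q), model_v(q)


def pseudo_snapshots(
    psi: np.ndarray, coeff: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Pseudo-snapshot matrix, one column per snapshot time.

    ``column i = phi @ coeff[i] @ psi`` with ``coeff`` of shape
    ``(Nt, Kx, Kc)``; returns ``(3*Nx, Nt)``.
    """
    reduced = np.einsum("tkl,l->kt", coeff, psi)
    return phi @ reduced


def local_pod(
    snapshots: np.ndarray,
    m: int | None = None,
    tol: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Local orthonormal basis: first ``m`` left singular vectors.

    Returns ``(basis, singular_values)``; ``m`` is clamped (with a
    warning) when it exceeds the available rank, and ``tol`` requests the
    smallest rank with tail energy below it.
    """
    U, s, _ = truncated_svd(snapshots, rank=m, tol=tol)
    return U, s


def coupling_matrix(phi_q: np.ndarray, gamma_q: np.ndarray) -> np.ndarray:
    """``Q = Phi_q^T Gamma_q`` (mu x mv); spectral norm <= 1 for
    orthonormal factors."""
    return phi_q.T @ gamma_q


def project_reduced_data(snapshots: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Orthogonal projection coefficients ``basis^T @ snapshots``.

    Column ``i`` holds the inner products of snapshot ``i`` with the basis
    vectors — the least-squares optimal coordinates for an orthonormal
    basis.
    """
    return basis.T @ snapshots


@dataclass
class Manifold:
    """Temporal diffuse-approximation model of ``xi = M(t, alpha)``.

    Coefficient vectors ``a_k(t)`` are fitted lazily at each requested
    time from the reduced data cloud ``(alpha_D(t_i), xi_D(t_i))`` using
    order-zero/one monomials in ``alpha`` and Wendland weights in time.
    """

    alpha_D: np.ndarray  # (mu, Nt)
    xi_D: np.ndarray  # (mv, Nt)
    times: np.ndarray  # (Nt,)
    window: float  # temporal kernel radius

    def __post_init__(self) -> None:
        self._regressors = np.column_stack(
            [np.ones(self.alpha_D.shape[1]), self.alpha_D.T]
        )  # (Nt, mu + 1)

    @property
    def mu(self) -> int:
        return self.alpha_D.shape[0]

    @property
    def mv(self) -> int:
        return self.xi_D.shape[0]

    def coefficients(self, t: float) -> np.ndarray:
        """Local coefficient matrix ``(mv, mu+1)`` at time ``t``."""
        return temporal_da_fit(
            self.times, self._regressors, self.xi_D.T, t, self.window
        )

    def eval(self, alpha: np.ndarray, t: float) -> np.ndarray:
        """``xi_k = p(alpha)^T a_k(t)`` for all k."""
        p = np.concatenate([[1.0], np.asarray(alpha, dtype=float)])
        return self.coefficients(t) @ p


def manifold_fit(
    alpha_D: np.ndarray,
    xi_D: np.ndarray,
    times: np.ndarray,
    t: float,
    window: float,
) -> np.ndarray:
    """Coefficient vectors ``a_k(t)``, stacked as a ``(mv, mu+1)`` matrix."""
    return Manifold(alpha_D, xi_D, np.asarray(times, dtype=float), window).coefficients(t)


def manifold_eval(alpha: np.ndarray, t: float, manifold: Manifold) -> np.ndarray:
    """Evaluate the learned manifold at reduced coordinates ``alpha``."""
    return manifold.eval(alpha, t)


@dataclass
class QueryModel:
    """Everything specific to one query parameter."""

    theta_q: ParameterPoint
    psi_u: np.ndarray  # (Kuc,)
    psi_v: np.ndarray  # (Kvc,)
    U_q: np.ndarray  # (3Nx, Nt) displacement pseudo-snapshots
    V_q: np.ndarray  # (3Nx, Nt) velocity pseudo-snapshots
    phi_q: np.ndarray  # (3Nx, mu) local displacement basis
    gamma_q: np.ndarray  # (3Nx, mv) local velocity basis
    Q: np.ndarray  # (mu, mv) coupling matrix
    alpha_D: np.ndarray  # (mu, Nt)
    xi_D: np.ndarray  # (mv, Nt)
    times: np.ndarray


@dataclass
class ROMTrajectory:
    """Integrated reduced coordinates on the ROM time grid."""

    dt_rom: float
    times: np.ndarray  # (n_steps + 1,)
    alpha: np.ndarray  # (mu, n_steps + 1)
    xi: np.ndarray  # (mv, n_steps + 1)
    manifold_coeffs: np.ndarray  # (n_steps + 1, mv, mu + 1)

    def index_of(self, t: float) -> int:
        i = int(round(t / self.dt_rom))
        if not (0 <= i < len(self.times)) or abs(self.times[i] - t) > 1e-9:
            raise ValueError(f"t={t} is not on the ROM time grid")
        return i


def build_query_model(
    theta_q: ParameterPoint,
    bases: GlobalBases,
    config: OnlineConfig = OnlineConfig(),
) -> QueryModel:
    """Steps (i)-(iv) of the online stage at one query parameter."""
    psi_u, psi_v = estimate_parametric_coordinates(theta_q, bases, config.da)
    U_q = pseudo_snapshots(psi_u, bases.A, bases.phi_u)
    V_q = pseudo_snapshots(psi_v, bases.B, bases.phi_v)
    phi_q, _ = local_pod(U_q, m=config.mu, tol=config.local_tol)
    gamma_q, _ = local_pod(V_q, m=config.mv, tol=config.local_tol)
    return QueryModel(
        theta_q=theta_q,
        psi_u=psi_u,
        psi_v=psi_v,
        U_q=U_q,
        V_q=V_q,
        phi_q=phi_q,
        gamma_q=gamma_q,
        Q=coupling_matrix(phi_q, gamma_q),
        alpha_D=project_reduced_data(U_q, phi_q),
        xi_D=project_reduced_data(V_q, gamma_q),
        times=bases.times.copy(),
    )


def rom_integrate(
    query_model: QueryModel,
    manifold: Manifold,
    dt_rom: float,
    t_final: float,
) -> ROMTrajectory:
    """Forward integration of the low-order dynamical system.

    Explicit recurrence ``alpha^{i+1} = alpha^i + dt_rom * Q xi^i``
    followed by the manifold closure for ``xi^{i+1}``; initialization
    ``alpha^0 = 0`` and ``xi^0`` from the manifold evaluated at ``t = 0``
    (the data grid starts at the first snapshot, so the ``t = 0`` value is
    the temporal fit extrapolated there).
    """
    if dt_rom <= 0:
        raise ValueError("dt_rom must be positive")
    n_steps = int(round(t_final / dt_rom))
    if n_steps < 1 or abs(n_steps * dt_rom - t_final) > 1e-9 * t_final:
        raise ValueError(f"t_final={t_final} is not a multiple of dt_rom={dt_rom}")
    Q = query_model.Q
    mu, mv = Q.shape
    times = dt_rom * np.arange(n_steps + 1)
    alpha = np.zeros((mu, n_steps + 1))
    xi = np.zeros((mv, n_steps + 1))
    coeffs = np.zeros((n_steps + 1, mv, mu + 1))
    coeffs[0] = manifold.coefficients(0.0)
    xi[:, 0] = coeffs[0] @ np.concatenate([[1.0], alpha[:, 0]])
    for i in range(n_steps):
        alpha[:, i + 1] = alpha[:, i] + dt_rom * (Q @ xi[:, i])
        if not np.all(np.isfinite(alpha[:, i + 1])):
            raise FloatingPointError(
                f"non-finite reduced state at step {i + 1} (t={times[i + 1]:g})"
            )
        coeffs[i + 1] = manifold.coefficients(times[i + 1])
        xi[:, i + 1] = coeffs[i + 1] @ np.concatenate([[1.0], alpha[:, i + 1]])
    return ROMTrajectory(
        dt_rom=dt_rom, times=times, alpha=alpha, xi=xi, manifold_coeffs=coeffs
    )


def reconstruct_fields(coords: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """High-dimensional field(s) from reduced coordinates: ``basis @ coords``."""
    return basis @ coords


def run_online(
    theta_q: ParameterPoint,
    bases: GlobalBases,
    config: OnlineConfig = OnlineConfig(),
) -> tuple[QueryModel, ROMTrajectory]:
    """Full online chain at one admissible query parameter.

    Returns the query model (local bases and reduced data) and the
    integrated trajectory; fields at any grid time follow from
    ``reconstruct_fields(trajectory.alpha[:, i], query_model.phi_q)``.
    """
    qm = build_query_model(theta_q, bases, config)
    dt_snap = float(qm.times[1] - qm.times[0]) if len(qm.times) > 1 else float(qm.times[0])
    dt_rom = config.dt_rom if config.dt_rom is not None else dt_snap / 2.0
    window = (
        config.temporal_window
        if config.temporal_window is not None
        else 2.0 * dt_snap
    )
    t_final = config.t_final if config.t_final is not None else float(qm.times[-1])
    manifold = Manifold(qm.alpha_D, qm.xi_D, qm.times, window)
    with warnings.catch_warnings():
        # Widening at t=0 (single snapshot in the initial window) is expected.
        warnings.simplefilter("ignore", UserWarning)
        traj = rom_integrate(qm, manifold, dt_rom, t_final)
    return qm, traj
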