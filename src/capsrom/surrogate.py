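"""Kinematic stand-in for the full-order fluid-structure solver.

The reduced-order pipeline is data-driven: it only sees nodal displacement
and velocity snapshots.  This module generates such snapshots from a closed
analytic form that reproduces the qualitative features of a capsule flowing
along a square microchannel — exponential relaxation toward a
parameter-dependent steady deformed shape, a parachute-like rear flattening
growing with Ca and confinement, and steady translation along the flow axis
at the duct centerline speed:

``u(X, t) = (1 - exp(-t/tau)) * [(F - I) X + c * g(X_z) e_z] + U_c t e_z``

with volume-preserving stretch ``F = diag(1-q, 1-q, (1-q)**-2)``,
deformation amplitude ``q = q0 * Ca * beta``, relaxation time
``tau = tau0 / (1 + Ca)``, parachute term ``g(X_z) = max(0, -X_z)**2`` of
amplitude ``c = parachute_gain * Ca * beta**2``, and translation speed
``U_c`` equal to the square-duct centerline Poiseuille velocity for unit
mean velocity.  The velocity field is the exact analytic time derivative.
All coefficients are smooth functions of ``(Ca, beta)``, which the diffuse
approximation stage requires.  Times are non-dimensional (``gamma_dot t``),
lengths in capsule radii.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datacube import DataCube, snapshot_count
from .geometry import CapsuleMesh
from .params import DesignOfExperiment, ParameterPoint, is_admissible
from .physics import poiseuille_square_velocity

__all__ = [
    "SurrogateParams",
    "surrogate_snapshot",
    "build_database",
    "finite_difference_velocity",
    "centerline_speed",
]


def centerline_speed() -> float:
    """Duct centerline velocity for unit mean velocity (about 2.096)."""
    return float(poiseuille_square_velocity(0.0, 0.0, V=1.0, ell=1.0))


@dataclass(frozen=True)
class SurrogateParams:
    """Coefficients of the synthetic snapshot generator.

    Defaults are chosen so that the steady shape is reached well before the
    final time (tau < 1) and the maximum deformation amplitude stays
    physical (``q < 0.3``) over the whole admissible domain.
    """

    q0: float = 1.2  # deformation gain, dimensionless
    tau0: float = 0.8  # relaxation time scale, units of 1/gamma_dot
    parachute_gain: float = 0.35  # axial-asymmetry gain
    translation_speed: float | None = None  # None -> duct centerline speed
    seed: int = 0
    noise_sd: float = 0.0  # sd of optional nodal perturbation, units of a

    def deformation_amplitude(self, theta: ParameterPoint) -> float:
        return self.q0 * theta.ca * theta.beta

    def relaxation_time(self, theta: ParameterPoint) -> float:
        return self.tau0 / (1.0 + theta.ca)

    def parachute_amplitude(self, theta: ParameterPoint) -> float:
        return self.parachute_gain * theta.ca * theta.beta**2

    def resolved_translation_speed(self) -> float:
        if self.translation_speed is not None:
            return self.translation_speed
        return centerline_speed()


def _steady_shape_increment(
    theta: ParameterPoint, X: np.ndarray, params: SurrogateParams
) -> np.ndarray:
    """(F - I) X + c g(X_z) e_z, flattened node-major; the relaxation target."""
    q = params.deformation_amplitude(theta)
    if not q < 1.0:
        raise ValueError(f"deformation amplitude q={q} must stay below 1")
    c = params.parachute_amplitude(theta)
    out = np.empty_like(X)
    out[:, 0] = -q * X[:, 0]
    out[:, 1] = -q * X[:, 1]
    out[:, 2] = ((1.0 - q) ** -2 - 1.0) * X[:, 2] + c * np.minimum(X[:, 2], 0.0) ** 2
    return out.ravel()


def surrogate_snapshot(
    theta: ParameterPoint,
    mesh: CapsuleMesh,
    t: float,
    params: SurrogateParams = SurrogateParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Displacement and velocity fields at one instant.

    Returns flattened ``(3*Nx,)`` arrays in the datacube component layout
    (node-major, (x, y, z) within node), in the laboratory frame.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    base = _steady_shape_increment(theta, mesh.vertices, params)
    tau = params.relaxation_time(theta)
    uc = params.resolved_translation_speed()
    decay = np.exp(-t / tau)
    u = (1.0 - decay) * base
    v = (decay / tau) * base
    u[2::3] += uc * t
    v[2::3] += uc
    return u, v


def build_database(
    doe: DesignOfExperiment,
    mesh: CapsuleMesh,
    dt: float,
    T: float,
    params: SurrogateParams = SurrogateParams(),
) -> DataCube:
    """Generate the full snapshot database over a design of experiment.

    Snapshots are taken at ``t_i = i * dt`` for ``i = 1..Nt`` with
    ``Nt = T / dt`` (the zero initial state is implicit).  With
    ``noise_sd = 0`` (the default) the database is deterministic and
    independent of the seed; otherwise an i.i.d. Gaussian nodal
    perturbation of that standard deviation is added to both fields.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    nt = snapshot_count(dt, T)
    bad = [j for j, p in enumerate(doe.points) if not is_admissible(p, doe.boundary)]
    if bad:
        raise ValueError(f"inadmissible DOE point(s) at indices {bad}")

    times = dt * np.arange(1, nt + 1)
    X = mesh.vertices
    n3 = 3 * X.shape[0]
    uc = params.resolved_translation_speed()
    u = np.empty((n3, nt, doe.n_points))
    v = np.empty((n3, nt, doe.n_points))
    for j, theta in enumerate(doe.points):
        base = _steady_shape_increment(theta, X, params)
        tau = params.relaxation_time(theta)
        decay = np.exp(-times / tau)  # (Nt,)
        u[:, :, j] = base[:, None] * (1.0 - decay)[None, :]
        v[:, :, j] = base[:, None] * (decay / tau)[None, :]
        u[2::3, :, j] += uc * times[None, :]
        v[2::3, :, j] += uc
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        u += rng.normal(0.0, params.noise_sd, u.shape)
        v += rng.normal(0.0, params.noise_sd, v.shape)
    return DataCube(
        u=u,
        v=v,
        times=times,
        doe=doe,
        mesh_ref=f"icosphere-level-{mesh.level}",
        provenance={
            "generator": "capsrom.surrogate",
            "params": {
                "q0": params.q0,
                "tau0": params.tau0,
                "parachute_gain": params.parachute_gain,
                "translation_speed": uc,
                "seed": params.seed,
                "noise_sd": params.noise_sd,
            },
            "dt": dt,
            "T": T,
        },
    )


def finite_difference_velocity(positions: np.ndarray, dt: float) -> np.ndarray:
    """Velocity snapshots from positions sampled uniformly in time.

    ``positions`` has time as its last axis.  Central second-order
    differences are used at interior times and one-sided second-order
    formulas at the two ends (first-order when only two levels exist).
    """
    positions = np.asarray(positions, dtype=float)
    nt = positions.shape[-1]
    if nt < 2:
        raise ValueError("need at least two time levels")
    if nt == 2:
        warnings.warn("two time levels: falling back to first-order slope")
        slope = (positions[..., 1] - positions[..., 0]) / dt
        return np.stack([slope, slope], axis=-1)
    return np.gradient(positions, dt, axis=-1, edge_order=2)


def predeformed_reference(mesh: CapsuleMesh, theta: ParameterPoint) -> CapsuleMesh:
    """Per-configuration reference mesh (pre-deformed at high confinement).

    The learned fields live on the shared spherical reference; the
    pre-deformation enters only when assembling laboratory positions,
    ``x = X_ref(beta) + u``.
    """
    from .geometry import predeform_ellipsoid

    return predeform_ellipsoid(mesh, theta.beta)
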