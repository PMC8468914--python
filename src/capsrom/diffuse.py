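"""Diffuse approximation: local weighted-least-squares polynomial regression.

A moving-least-squares variant used twice in the pipeline: over the
two-dimensional parameter plane (anisotropic elliptic neighborhoods of the
``M`` nearest samples, compactly supported Wendland kernel, polynomial basis
of order one or two) to interpolate parametric POD coordinates at a query
point, and over the time axis (order-one monomials in the reduced
displacement coordinates, temporal Wendland weights) to learn the
displacement-to-velocity manifold.

The weighted least-squares problem ``min_A sum_k w_k |A p(x_k) - y_k|^2``
has the closed-form solution ``A = Y^T W P (P^T W P)^{-1}``; the solver
works on the square-root-weighted system with an orthogonal factorization
instead of forming normal equations, and agrees with the closed form to
1e-10 on well-conditioned inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "DAConfig",
    "DAModel",
    "polynomial_basis",
    "elliptic_distance",
    "wendland_weight",
    "select_neighborhood",
    "wls_fit",
    "fit_parameter_da",
    "temporal_da_fit",
]


@dataclass(frozen=True)
class DAConfig:
    """Settings of the parameter-space diffuse approximation.

    ``order`` 1 uses the basis ``(1, Ca, beta)`` (m = 3); order 2 adds the
    cross and square terms (m = 6).  ``neighbor_count`` is the number of
    samples inside the elliptic support, ``r_tilde`` the anisotropy ratio
    weighting the beta axis.  ``ridge=None`` applies a scale-aware
    regularization ``1e-12 * trace(P^T W P) / m``; set ``ridge=0.0`` for
    the exact unregularized closed form.
    """

    order: int = 2
    neighbor_count: int = 12
    r_tilde: float = 1.9
    ridge: float | None = None

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ValueError("DA order must be 1 or 2")
        if self.neighbor_count < self.basis_size:
            raise ValueError(
                f"need at least m={self.basis_size} neighbors for order "
                f"{self.order}, got M={self.neighbor_count}"
            )

    @property
    def basis_size(self) -> int:
        return 3 if self.order == 1 else 6


def polynomial_basis(theta: np.ndarray, order: int) -> np.ndarray:
    """Monomial vector(s) of the parameter pair.

    Order 1: ``(1, Ca, beta)``; order 2 appends ``(Ca*beta, Ca^2, beta^2)``.
    Accepts a single ``(2,)`` point or an ``(N, 2)`` batch.
    """
    if order not in (1, 2):
        raise ValueError("DA order must be 1 or 2")
    th = np.atleast_2d(np.asarray(theta, dtype=float))
    ca, beta = th[:, 0], th[:, 1]
    cols = [np.ones_like(ca), ca, beta]
    if order == 2:
        cols += [ca * beta, ca**2, beta**2]
    out = np.column_stack(cols)
    return out[0] if np.asarray(theta).ndim == 1 else out


def elliptic_distance(
    theta: np.ndarray,
    theta_q: np.ndarray,
    r_tilde: float = 1.9,
    R: float = 1.0,
) -> np.ndarray:
    """Anisotropic distance ``sqrt(dCa^2 + r_tilde^2 dbeta^2) / R``."""
    th = np.atleast_2d(np.asarray(theta, dtype=float))
    tq = np.asarray(theta_q, dtype=float)
    d = np.sqrt(
        (th[:, 0] - tq[0]) ** 2 + r_tilde**2 * (th[:, 1] - tq[1]) ** 2
    ) / R
    return float(d[0]) if np.asarray(theta).ndim == 1 else d


def wendland_weight(d: float | np.ndarray) -> float | np.ndarray:
    """Compactly supported kernel ``w(d) = 2d^3 - 3d^2 + 1`` on [0, 1].

    Continuous, monotone non-increasing, ``w(0) = 1``, ``w(d >= 1) = 0``.
    """
    d = np.asarray(d, dtype=float)
    w = np.where(d <= 1.0, 2.0 * d**3 - 3.0 * d**2 + 1.0, 0.0)
    w = np.maximum(w, 0.0)
    return float(w) if w.ndim == 0 else w


def select_neighborhood(
    theta_q: np.ndarray,
    samples: np.ndarray,
    M: int,
    r_tilde: float = 1.9,
) -> tuple[np.ndarray, float]:
    """The ``M`` nearest samples in the anisotropic metric, and the support
    radius ``R``.

    ``R`` is set to the distance of the ``(M+1)``-th nearest sample so that
    every selected point lies strictly inside the support ellipse and
    carries a positive weight.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.shape[0] < M + 1:
        raise ValueError(
            f"need at least M+1={M + 1} samples to size the support, "
            f"got {samples.shape[0]}"
        )
    d = elliptic_distance(samples, theta_q, r_tilde=r_tilde, R=1.0)
    order = np.argsort(d, kind="stable")
    R = float(d[order[M]])
    if R <= 0.0:
        raise ValueError("support radius degenerated to zero (duplicate samples)")
    return order[:M], R


def wls_fit(
    P: np.ndarray,
    w: np.ndarray,
    Y: np.ndarray,
    ridge: float = 0.0,
    on_singular: str = "raise",
) -> np.ndarray:
    """Solve the weighted least-squares problem for the coefficient matrix.

    Parameters
    ----------
    P:
        ``(n, m)`` design matrix of basis vectors at the support points.
    w:
        ``(n,)`` non-negative weights.
    Y:
        ``(n, K)`` responses (one column per output).
    ridge:
        Tikhonov parameter added to ``P^T W P``; 0 reproduces the exact
        closed form.
    on_singular:
        ``"raise"`` raises on a rank-deficient system (local point
        alignment); ``"minnorm"`` returns the minimum-norm solution.

    Returns the ``(K, m)`` coefficient matrix ``A`` with fitted values
    ``A @ p(x)``.
    """
    P = np.asarray(P, dtype=float)
    w = np.asarray(w, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = P.shape
    positive = w > 0
    if positive.sum() < 1:
        raise ValueError("no support point has positive weight")
    sw = np.sqrt(w[positive])
    Pw = P[positive] * sw[:, None]
    Yw = Y[positive] * sw[:, None]
    if ridge > 0.0:
        G = Pw.T @ Pw + ridge * np.eye(m)
        return linalg.solve(G, Pw.T @ Yw, assume_a="pos").T
    coeffs, _, rank, _ = linalg.lstsq(Pw, Yw, lapack_driver="gelsd")
    if rank < m:
        if on_singular == "raise":
            raise np.linalg.LinAlgError(
                f"rank-deficient weighted least squares (rank {rank} < m={m}); "
                "support points are locally aligned"
            )
        if on_singular != "minnorm":
            raise ValueError(f"unknown on_singular mode {on_singular!r}")
    return coeffs.T


@dataclass
class DAModel:
    """A fitted local polynomial model around one query point.

    The fit is performed in query-centered coordinates scaled by the
    support radius (``z = (theta - theta_q) / scale``), which keeps the
    normal matrix well conditioned; for a polynomial basis this affine
    change of variables leaves the fitted polynomial — hence every
    prediction — identical to the raw-monomial closed form.
    """

    coeffs: np.ndarray  # (K, m), w.r.t. the centered-scaled basis
    support: np.ndarray  # indices of samples used
    R: float  # support ellipse radius
    center: np.ndarray  # theta_q
    scale: np.ndarray  # per-axis scaling of the centered coordinates
    order: int
    weights: np.ndarray = field(repr=False, default=None)

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        z = (np.asarray(theta, dtype=float) - self.center) / self.scale
        return self.coeffs @ polynomial_basis(z, self.order)


def fit_parameter_da(
    theta_q: np.ndarray,
    samples: np.ndarray,
    Y: np.ndarray,
    config: DAConfig = DAConfig(),
) -> DAModel:
    """Fit the parameter-space diffuse approximation at one query point.

    ``Y`` holds one row of responses per sample (``(Nc, K)``); typically
    the truncated parametric mode matrix, whose row ``j`` carries the POD
    coordinates of configuration ``j``.
    """
    theta_q = np.asarray(theta_q, dtype=float)
    samples = np.asarray(samples, dtype=float)
    idx, R = select_neighborhood(
        theta_q, samples, config.neighbor_count, config.r_tilde
    )
    d = elliptic_distance(samples[idx], theta_q, r_tilde=config.r_tilde, R=R)
    w = wendland_weight(d)
    scale = np.array([R, R / config.r_tilde])
    z = (samples[idx] - theta_q) / scale
    # Gridded designs can align a neighborhood on few rows, leaving the
    # basis rank-deficient (e.g. two distinct beta values cannot identify
    # beta^2).  The fit at the query is still well defined whenever the
    # evaluation functional — the intercept of the centered basis — is
    # estimable (lies in the row space of the weighted design); then the
    # minimum-norm solution is unbiased at the query.  Otherwise degrade
    # the basis order before declaring the cloud degenerate.
    coeffs = None
    for order in range(config.order, 0, -1):
        P = polynomial_basis(z, order)
        m = P.shape[1]
        Pw = P * np.sqrt(w)[:, None]
        smax = linalg.svdvals(Pw)[0]
        if np.linalg.matrix_rank(Pw, tol=1e-8 * smax) == m:
            if config.ridge is None:
                ridge = 1e-12 * np.trace(Pw.T @ Pw) / m
            else:
                ridge = config.ridge
            coeffs = wls_fit(P, w, np.asarray(Y)[idx], ridge=ridge)
            break
        e1 = np.zeros(m)
        e1[0] = 1.0
        x, *_ = linalg.lstsq(Pw.T, e1, lapack_driver="gelsd")
        if np.linalg.norm(Pw.T @ x - e1) <= 1e-8:
            coeffs = wls_fit(P, w, np.asarray(Y)[idx], ridge=0.0, on_singular="minnorm")
            break
        if order > 1:
            warnings.warn(
                f"rank-deficient order-{order} neighborhood at "
                f"theta={theta_q}; falling back to order {order - 1}"
            )
    if coeffs is None:
        raise np.linalg.LinAlgError(
            "degenerate diffuse-approximation neighborhood: support points "
            "are locally aligned"
        )
    return DAModel(
        coeffs=coeffs,
        support=idx,
        R=R,
        center=theta_q,
        scale=scale,
        order=order,
        weights=w,
    )


def temporal_da_fit(
    times: np.ndarray,
    regressors: np.ndarray,
    responses: np.ndarray,
    t_query: float,
    window: float,
) -> np.ndarray:
    """Moving local fit along the time axis.

    ``regressors`` is the ``(Nt, m)`` design matrix (for the manifold, the
    order-zero/one monomials of the reduced displacement coordinates) and
    ``responses`` the ``(Nt, K)`` outputs; weights are
    ``w(|t - t_i| / window)``.  If fewer than two snapshots fall inside the
    window it is widened (doubling, with a warning) until two do.  The
    generically rank-deficient system (narrow windows hold at most three
    snapshots) is resolved by the minimum-norm solution.

    Returns the ``(K, m)`` coefficient matrix at ``t_query``.
    """
    times = np.asarray(times, dtype=float)
    if window <= 0:
        raise ValueError("temporal window must be positive")
    w = wendland_weight(np.abs(times - t_query) / window)
    grown = window
    while (w > 0).sum() < 2:
        grown *= 2.0
        if grown > 1e6 * (times[-1] - times[0] + window):
            raise ValueError("temporal window widening failed to find snapshots")
        warnings.warn(
            f"temporal DA window widened to {grown:g} near t={t_query:g}"
        )
        w = wendland_weight(np.abs(times - t_query) / grown)
    P = np.asarray(regressors, dtype=float)
    if P.shape[1] > 1 and np.all(P[:, 0] == 1.0):
        # Center the non-constant regressors by their kernel-weighted mean:
        # the intercept column becomes W-orthogonal to them, so the
        # minimum-norm solution leaves constant responses entirely to the
        # intercept instead of spreading them across slope coefficients.
        zbar = (w @ P[:, 1:]) / np.sum(w)
        Pc = P.copy()
        Pc[:, 1:] -= zbar
        coeffs = wls_fit(Pc, w, responses, ridge=0.0, on_singular="minnorm")
        coeffs[:, 0] -= coeffs[:, 1:] @ zbar
        return coeffs
    return wls_fit(P, w, responses, ridge=0.0, on_singular="minnorm")
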