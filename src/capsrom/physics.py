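"""Physical utility formulas: duct flow profile and membrane tensions.

``poiseuille_square_velocity`` evaluates the classical Fourier-series
solution for fully developed laminar flow in a duct of square cross-section
(walls at ``x, y = +/- l/2`` in the series' own scaling).  Because the
printed closed-form normalization of the series is easy to mistranscribe,
the truncated series is renormalized by its numerically computed
cross-sectional mean, which enforces the defining property that ``V`` is the
mean velocity, exactly, at any truncation.

``nh_tensions`` gives the principal Cauchy in-plane tensions of a
Neo-Hookean membrane (an infinitely thin sheet of an isotropic,
incompressible 3-D material) as a function of the principal extension
ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = ["poiseuille_square_velocity", "nh_tensions", "MembraneState"]

#: Number of odd harmonics kept in the duct-flow series (n = 1, 3, ..,
#: 2*N_TERMS_DEFAULT - 1).
N_TERMS_DEFAULT = 51


def _series(sx: np.ndarray, sy: np.ndarray, n_terms: int) -> np.ndarray:
    """Unnormalized series at scaled coordinates sx in [-1/2, 1/2], sy = y/l."""
    out = np.zeros(np.broadcast(sx, sy).shape)
    for n in range(1, 2 * n_terms, 2):
        out += (
            (np.pi / n**3)
            * (1.0 - np.cosh(n * np.pi * sx) / np.cosh(n * np.pi / 2.0))
            * np.sin(n * np.pi * (sy + 0.5))
        )
    return out


@lru_cache(maxsize=None)
def _mean_factor(n_terms: int) -> float:
    """Exact cross-sectional mean of the unnormalized truncated series.

    Each harmonic integrates in closed form:
    ``(2/n**4) * (1 - 2 tanh(n pi / 2) / (n pi))`` for odd ``n``.
    """
    total = 0.0
    for n in range(1, 2 * n_terms, 2):
        total += (2.0 / n**4) * (1.0 - 2.0 * np.tanh(n * np.pi / 2.0) / (n * np.pi))
    return float(total)


def poiseuille_square_velocity(
    x: float | np.ndarray,
    y: float | np.ndarray,
    V: float = 1.0,
    ell: float = 1.0,
    n_terms: int = N_TERMS_DEFAULT,
) -> float | np.ndarray:
    """Axial velocity of square-duct Poiseuille flow at cross-section point.

    Parameters
    ----------
    x, y:
        Cross-section coordinates; the walls sit at ``+/- ell/2``.
    V:
        Mean velocity over the cross-section (enforced exactly).
    ell:
        Duct width scale appearing in the series (wall-to-wall distance).
    n_terms:
        Number of odd harmonics retained; the default resolves the profile
        far below double precision away from the corners.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    half = 0.5 * ell + 1e-12 * ell
    if np.any(np.abs(x) > half) or np.any(np.abs(y) > half):
        raise ValueError("point outside the square cross-section")
    vals = V * _series(x / ell, y / ell, n_terms) / _mean_factor(n_terms)
    # The exact profile is non-negative; clip truncation undershoot at walls.
    vals = np.maximum(vals, 0.0)
    return float(vals) if vals.ndim == 0 else vals


def nh_tensions(
    lambda1: float | np.ndarray,
    lambda2: float | np.ndarray,
    Gs: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Principal Cauchy tensions of a Neo-Hookean membrane.

    ``tau_1 = Gs / (l1 l2) * (l1**2 - 1 / (l1**2 l2**2))`` and
    symmetrically for ``tau_2``; both vanish in the undeformed state
    ``l1 = l2 = 1``.  ``Gs`` is the surface shear modulus (the area
    expansion modulus of this law is ``Ks = 3 Gs``).
    """
    l1 = np.asarray(lambda1, dtype=float)
    l2 = np.asarray(lambda2, dtype=float)
    if np.any(l1 <= 0) or np.any(l2 <= 0):
        raise ValueError("extension ratios must be positive")
    inv = 1.0 / (l1**2 * l2**2)
    tau1 = Gs / (l1 * l2) * (l1**2 - inv)
    tau2 = Gs / (l1 * l2) * (l2**2 - inv)
    return tau1, tau2


@dataclass(frozen=True)
class MembraneState:
    """Local membrane state: principal stretches and resulting tensions.

    ``Ks = 3 Gs`` is the area expansion modulus of the Neo-Hookean surface
    law; tensions are forces per unit arc length of the deformed surface
    and vanish in the undeformed state.
    """

    lambda1: float
    lambda2: float
    Gs: float = 1.0
    tau1: float = field(init=False)
    tau2: float = field(init=False)

    def __post_init__(self) -> None:
        t1, t2 = nh_tensions(self.lambda1, self.lambda2, self.Gs)
        object.__setattr__(self, "tau1", float(t1))
        object.__setattr__(self, "tau2", float(t2))

    @property
    def Ks(self) -> float:
        return 3.0 * self.Gs
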