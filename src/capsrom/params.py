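"""Parameter domain of the capsule flow problem.

The governing parameters are the capillary number ``Ca`` (viscous over
elastic membrane forces) and the confinement ratio ``beta = a / l`` (capsule
radius over channel half-width scale).  Only configurations that reach a
steady deformed shape are admissible; above a critical capillary number the
membrane elongates continuously and no steady state exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

__all__ = [
    "ParameterPoint",
    "DesignOfExperiment",
    "steady_state_boundary",
    "is_admissible",
    "build_doe",
]

CA_MIN, CA_MAX = 0.005, 0.2
BETA_MIN, BETA_MAX = 0.75, 1.2

#: Grid steps of the reference Cartesian parameter sampling.
CA_STEP_DEFAULT = 0.01
BETA_STEP_DEFAULT = 0.05


@dataclass(frozen=True)
class ParameterPoint:
    """A (Ca, a/l) parameter pair; the coordinate of all interpolation."""

    ca: float
    beta: float

    def __post_init__(self) -> None:
        if not (CA_MIN <= self.ca <= CA_MAX):
            raise ValueError(
                f"Ca={self.ca} outside admissible range [{CA_MIN}, {CA_MAX}]"
            )
        if not (BETA_MIN <= self.beta <= BETA_MAX):
            raise ValueError(
                f"a/l={self.beta} outside admissible range "
                f"[{BETA_MIN}, {BETA_MAX}]"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.ca, self.beta])


def steady_state_boundary(beta: float | np.ndarray) -> float | np.ndarray:
    """Synthetic steady-state limit ``Ca_max(beta) = 0.27 - 0.125 beta``.

    A stand-in for the (unpublished) critical capillary number above which
    the capsule elongates continuously: a straight line decreasing with
    confinement, matching the qualitative trend of the physical boundary.
    This is a property of the synthetic study, not a measured value.
    """
    return 0.27 - 0.125 * np.asarray(beta)


def is_admissible(
    theta: ParameterPoint,
    boundary: Callable[[float], float] = steady_state_boundary,
) -> bool:
    """True when ``theta`` lies in the box and below the steady boundary."""
    return bool(theta.ca <= boundary(theta.beta) + 1e-12)


@dataclass
class DesignOfExperiment:
    """A Cartesian design of experiment over the admissible domain.

    ``cluster_labels[i]`` is 1, 2 or 0 (overlap band) once a cluster
    partition has been applied; ``None`` before that.
    """

    points: list[ParameterPoint]
    ca_step: float = CA_STEP_DEFAULT
    beta_step: float = BETA_STEP_DEFAULT
    boundary: Callable[[float], float] = field(
        default=steady_state_boundary, repr=False
    )
    cluster_labels: np.ndarray | None = None

    @property
    def n_points(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        """``(Nc, 2)`` array of (Ca, beta) rows."""
        return np.array([[p.ca, p.beta] for p in self.points])

    def boundary_mask(self) -> np.ndarray:
        """Mark design points on the edge of the admissible sampling.

        A point is a boundary point when any of its four Cartesian grid
        neighbors ``(Ca +/- ca_step, beta)``, ``(Ca, beta +/- beta_step)``
        is absent from the design (off-grid Ca refinements such as the
        extra low-Ca column count as boundary).
        """
        pts = self.as_array()
        have = {(round(c, 9), round(b, 9)) for c, b in pts}
        mask = np.zeros(self.n_points, dtype=bool)
        for i, (c, b) in enumerate(pts):
            for dc, db in (
                (self.ca_step, 0.0),
                (-self.ca_step, 0.0),
                (0.0, self.beta_step),
                (0.0, -self.beta_step),
            ):
                if (round(c + dc, 9), round(b + db, 9)) not in have:
                    mask[i] = True
                    break
        return mask


def build_doe(
    ca_step: float = CA_STEP_DEFAULT,
    beta_step: float = BETA_STEP_DEFAULT,
    extra_ca: Iterable[float] = (0.005,),
    boundary: Callable[[float], float] = steady_state_boundary,
) -> DesignOfExperiment:
    """Cartesian sampling of the admissible parameter domain.

    Ca runs from ``ca_step`` to 0.2 in steps of ``ca_step`` plus the extra
    low-Ca values; beta runs from 0.75 to 1.2 in steps of ``beta_step``.
    Points above the steady-state boundary are dropped.
    """
    n_ca = int(round(CA_MAX / ca_step))
    cas = sorted(
        set(np.round(np.arange(1, n_ca + 1) * ca_step, 9))
        | {round(c, 9) for c in extra_ca}
    )
    n_b = int(round((BETA_MAX - BETA_MIN) / beta_step))
    betas = np.round(BETA_MIN + np.arange(n_b + 1) * beta_step, 9)
    points = [
        ParameterPoint(ca, b)
        for b in betas
        for ca in cas
        if CA_MIN <= ca <= CA_MAX and ca <= boundary(b) + 1e-12
    ]
    return DesignOfExperiment(
        points=points, ca_step=ca_step, beta_step=beta_step, boundary=boundary
    )
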