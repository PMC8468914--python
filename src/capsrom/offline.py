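"""Offline stage: double POD bases, truncation, and coefficient matrices.

Two singular value decompositions summarize the snapshot datacube of each
field (displacement ``u`` and velocity ``v``): the parametric stack yields
discrete parameter modes (right singular vectors over configurations), the
spatial stack yields spatial modes (left singular vectors over the 3*Nx
degrees of freedom).  Truncation is by fixed rank or by relative
information content, and per-snapshot coefficient matrices

``A(t_i) = Phi_u^T  u(., t_i, .)  Psi_u``   (and ``B(t_i)`` for velocity)

compress the datacube to ``Nt`` small matrices.  SVD sign indeterminacy is
removed by forcing the largest-magnitude entry of every left mode to be
positive, making the offline stage bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg

from .datacube import DataCube, stack_parametric, stack_spatial
from .params import DesignOfExperiment, ParameterPoint

__all__ = [
    "OfflineConfig",
    "GlobalBases",
    "ClusterPartition",
    "truncated_svd",
    "relative_information_content",
    "decay_ratio",
    "rank_for_tolerance",
    "coefficient_matrices",
    "run_offline",
    "assign_cluster",
    "save_bases",
    "load_bases",
]


# ---------------------------------------------------------------------------
# SVD with canonical signs, information content
# ---------------------------------------------------------------------------


def _canonical_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip mode pairs so each left mode's largest-|entry| is positive."""
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, V * signs


def truncated_svd(
    matrix: np.ndarray,
    rank: int | None = None,
    tol: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thin SVD with canonical signs and optional truncation.

    Returns ``(U_K, s, V_K)`` where ``s`` holds *all* singular values
    (non-negative, non-increasing) and ``U_K``/``V_K`` the first ``K``
    left/right modes as columns.  ``rank`` requests a fixed ``K`` (clamped
    with a warning if it exceeds the available rank); ``tol`` requests the
    smallest ``K`` with tail energy ``1 - RIC(K) <= tol``.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("cannot decompose an empty matrix")
    U, s, Vt = linalg.svd(matrix, full_matrices=False, lapack_driver="gesdd")
    V = Vt.T
    U, V = _canonical_signs(U, V)
    r = len(s)
    if rank is None and tol is None:
        K = r
    elif tol is not None:
        K = rank_for_tolerance(s, tol)
        if rank is not None:
            K = min(K, rank)
    else:
        K = int(rank)
        if K > r:
            warnings.warn(
                f"requested rank {K} exceeds available rank {r}; clamping"
            )
            K = r
    if K < 1:
        raise ValueError("truncation rank must be at least 1")
    return U[:, :K], s, V[:, :K]


def _gram_modes(
    matrix: np.ndarray,
    side: str,
    rank: int | None,
    tol: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Singular modes of one side via the smaller Gram matrix.

    ``side='right'`` returns the right singular vectors from
    ``eigh(M^T M)``; ``side='left'`` the left ones from ``eigh(M M^T)``.
    Exact and deterministic (symmetric eigensolver); modes below the
    square-root-of-machine-precision level lose directional accuracy, but
    they carry no information and stay exactly orthonormal.  Far cheaper
    than a full SVD when one dimension is much smaller.  Returns
    ``(modes_K, all_singular_values)`` with canonical signs.
    """
    G = matrix.T @ matrix if side == "right" else matrix @ matrix.T
    lam, vec = linalg.eigh(G)
    order = np.argsort(lam)[::-1]
    lam = np.maximum(lam[order], 0.0)
    vec = vec[:, order]
    s = np.sqrt(lam)
    idx = np.argmax(np.abs(vec), axis=0)
    signs = np.sign(vec[idx, np.arange(vec.shape[1])])
    signs[signs == 0] = 1.0
    vec = vec * signs
    r = len(s)
    if tol is not None:
        K = rank_for_tolerance(s, tol)
    elif rank is not None:
        K = int(rank)
        if K > r:
            warnings.warn(f"requested rank {K} exceeds available rank {r}; clamping")
            K = r
    else:
        K = r
    return vec[:, :K], s


def relative_information_content(singulars: np.ndarray, K: int) -> float:
    """Fraction of squared singular-value energy captured by K modes."""
    s = np.asarray(singulars, dtype=float)
    total = float(np.sum(s**2))
    if total == 0.0:
        raise ValueError("all singular values are zero")
    if not 0 <= K <= len(s):
        raise ValueError(f"K={K} outside [0, {len(s)}]")
    return float(np.sum(s[:K] ** 2) / total)


def decay_ratio(singulars: np.ndarray, K: int) -> float:
    """Singular-value decay indicator ``sigma_K / sigma_1`` (1-indexed)."""
    s = np.asarray(singulars, dtype=float)
    if not 1 <= K <= len(s):
        raise ValueError(f"K={K} outside [1, {len(s)}]")
    if s[0] == 0.0:
        raise ValueError("leading singular value is zero")
    return float(s[K - 1] / s[0])


def rank_for_tolerance(singulars: np.ndarray, tol: float) -> int:
    """Minimal K with tail energy ``1 - RIC(K) <= tol``."""
    s = np.asarray(singulars, dtype=float)
    total = float(np.sum(s**2))
    if total == 0.0:
        raise ValueError("all singular values are zero")
    tail = 1.0 - np.cumsum(s**2) / total
    hits = np.nonzero(tail <= tol + 1e-300)[0]
    return int(hits[0]) + 1 if hits.size else len(s)


# ---------------------------------------------------------------------------
# Global bases
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OfflineConfig:
    """Truncation settings of the offline stage.

    Fixed ranks are the defaults; setting ``tol`` switches to
    tolerance-driven truncation (smallest rank with ``1 - RIC <= tol``).
    """

    k_u_x: int = 40
    k_u_c: int = 40
    k_v_x: int = 50
    k_v_c: int = 50
    tol: float | None = None


@dataclass
class GlobalBases:
    """Outputs of the offline stage for one snapshot database."""

    phi_u: np.ndarray  # (3Nx, Kux) spatial displacement modes
    phi_v: np.ndarray  # (3Nx, Kvx) spatial velocity modes
    psi_u: np.ndarray  # (Nc, Kuc) parametric displacement modes
    psi_v: np.ndarray  # (Nc, Kvc) parametric velocity modes
    sing_S_u: np.ndarray
    sing_S_v: np.ndarray
    sing_T_u: np.ndarray
    sing_T_v: np.ndarray
    A: np.ndarray  # (Nt, Kux, Kuc)
    B: np.ndarray  # (Nt, Kvx, Kvc)
    times: np.ndarray
    doe_points: np.ndarray  # (Nc, 2)

    @property
    def ranks(self) -> dict[str, int]:
        return {
            "k_u_x": self.phi_u.shape[1],
            "k_u_c": self.psi_u.shape[1],
            "k_v_x": self.phi_v.shape[1],
            "k_v_c": self.psi_v.shape[1],
        }


def coefficient_matrices(
    cube: DataCube,
    phi_u: np.ndarray,
    psi_u: np.ndarray,
    phi_v: np.ndarray,
    psi_v: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-snapshot coefficient matrices ``A(t_i)``, ``B(t_i)``.

    ``A[i] = phi_u^T @ u(., t_i, .) @ psi_u`` of shape (Kux, Kuc); ``B``
    analogously from the velocity field.
    """
    if phi_u.shape[0] != 3 * cube.nx or psi_u.shape[0] != cube.nc:
        raise ValueError("basis dimensions do not match the datacube")
    if phi_v.shape[0] != 3 * cube.nx or psi_v.shape[0] != cube.nc:
        raise ValueError("basis dimensions do not match the datacube")
    A = np.einsum("xk,xtc,cl->tkl", phi_u, cube.u, psi_u, optimize=True)
    B = np.einsum("xk,xtc,cl->tkl", phi_v, cube.v, psi_v, optimize=True)
    return A, B


def run_offline(cube: DataCube, config: OfflineConfig = OfflineConfig()) -> GlobalBases:
    """Full offline stage: stacking, SVDs, truncation, coefficient matrices."""
    ranks = {}
    modes = {}
    sing = {}
    for name in ("u", "v"):
        kx = config.k_u_x if name == "u" else config.k_v_x
        kc = config.k_u_c if name == "u" else config.k_v_c
        S = stack_parametric(cube, name).values
        psi, s_S = _gram_modes(
            S, "right", rank=None if config.tol is not None else kc, tol=config.tol
        )
        T = stack_spatial(cube, name).values
        phi, s_T = _gram_modes(
            T, "left", rank=None if config.tol is not None else kx, tol=config.tol
        )
        modes[f"phi_{name}"] = phi
        modes[f"psi_{name}"] = psi
        sing[f"S_{name}"] = s_S
        sing[f"T_{name}"] = s_T
        ranks[name] = (phi.shape[1], psi.shape[1])
    A, B = coefficient_matrices(
        cube, modes["phi_u"], modes["psi_u"], modes["phi_v"], modes["psi_v"]
    )
    return GlobalBases(
        phi_u=modes["phi_u"],
        phi_v=modes["phi_v"],
        psi_u=modes["psi_u"],
        psi_v=modes["psi_v"],
        sing_S_u=sing["S_u"],
        sing_S_v=sing["S_v"],
        sing_T_u=sing["T_u"],
        sing_T_v=sing["T_v"],
        A=A,
        B=B,
        times=cube.times.copy(),
        doe_points=cube.doe.as_array(),
    )


# ---------------------------------------------------------------------------
# Parameter-domain clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterPartition:
    """Two weakly overlapping rectangles splitting the domain in Ca.

    Cluster 1 covers ``Ca <= ca_split + overlap/2``, cluster 2 covers
    ``Ca >= ca_split - overlap/2``; the band in between belongs to both.
    A one-cluster partition (``n_clusters=1``) disables the split.
    """

    ca_split: float = 0.10
    overlap: float = 0.02
    n_clusters: int = 2

    def membership(self, theta: ParameterPoint) -> tuple[bool, bool]:
        if self.n_clusters == 1:
            return True, False
        lo = theta.ca <= self.ca_split + self.overlap / 2 + 1e-12
        hi = theta.ca >= self.ca_split - self.overlap / 2 - 1e-12
        return lo, hi

    def labels(self, doe: DesignOfExperiment) -> np.ndarray:
        """Per-point label: 1, 2, or 0 for the overlap band."""
        out = np.empty(doe.n_points, dtype=int)
        for i, p in enumerate(doe.points):
            lo, hi = self.membership(p)
            out[i] = 0 if (lo and hi) else (1 if lo else 2)
        return out

    def member_indices(self, doe: DesignOfExperiment, cluster_id: int) -> np.ndarray:
        """Indices of DOE points belonging to a cluster (overlap included)."""
        members = []
        for i, p in enumerate(doe.points):
            lo, hi = self.membership(p)
            if (cluster_id == 1 and lo) or (cluster_id == 2 and hi):
                members.append(i)
        return np.asarray(members, dtype=int)


def assign_cluster(
    theta: ParameterPoint,
    partition: ClusterPartition,
    doe: DesignOfExperiment,
) -> int:
    """Cluster of belonging for a query point.

    Inside the overlap band the nearest-cluster-centroid rule applies
    (centroids of the exclusive members); exact ties go to the lower id.
    """
    lo, hi = partition.membership(theta)
    if lo and not hi:
        return 1
    if hi and not lo:
        return 2
    if not (lo or hi):
        raise ValueError(f"query {theta} belongs to no cluster")
    if partition.n_clusters == 1:
        return 1
    labels = partition.labels(doe)
    pts = doe.as_array()
    q = theta.as_array()
    dists = []
    for cid in (1, 2):
        own = pts[labels == cid]
        if len(own) == 0:
            own = pts[partition.member_indices(doe, cid)]
        dists.append(np.linalg.norm(own.mean(axis=0) - q))
    return 1 if dists[0] <= dists[1] else 2


# ---------------------------------------------------------------------------
# Model persistence (binary arrays + JSON manifest)
# ---------------------------------------------------------------------------

_ARRAY_FIELDS = (
    "phi_u", "phi_v", "psi_u", "psi_v",
    "sing_S_u", "sing_S_v", "sing_T_u", "sing_T_v",
    "A", "B", "times", "doe_points",
)

_MODEL_VERSION = 1


def save_bases(bases: GlobalBases, path: str | Path) -> None:
    """Persist global bases as per-array ``.bin`` files plus a manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"version": _MODEL_VERSION, "arrays": {}}
    for name in _ARRAY_FIELDS:
        arr = np.asarray(getattr(bases, name), dtype=float)
        arr.astype("<f8").tofile(path / f"{name}.bin")
        manifest["arrays"][name] = list(arr.shape)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_bases(path: str | Path) -> GlobalBases:
    path = Path(path)
    try:
        manifest = json.loads((path / "manifest.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot read model manifest in {path}: {exc}") from exc
    if manifest.get("version") != _MODEL_VERSION:
        raise ValueError(f"unsupported model version {manifest.get('version')!r}")
    arrays = {}
    for name in _ARRAY_FIELDS:
        shape = tuple(manifest["arrays"][name])
        data = np.fromfile(path / f"{name}.bin", dtype="<f8")
        if data.size != int(np.prod(shape)):
            raise ValueError(f"{name}.bin does not match its declared shape")
        arrays[name] = data.reshape(shape)
    return GlobalBases(**arrays)
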