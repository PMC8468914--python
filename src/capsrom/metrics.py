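"""Shape-accuracy metrics and leave-one-out cross-validation.

The headline error measure is the modified Hausdorff distance between two
finite point sets (capsule surfaces at one instant): the maximum of the two
directed *mean* nearest-point distances.  Unlike the classical Hausdorff
distance it averages rather than maximizes over points, making it robust to
single outlying nodes; it is normalized by the capsule radius ``a``.

Leave-one-out cross-validation removes one design configuration, rebuilds
the offline model from the remaining snapshots, predicts the withheld
configuration with the online stage, and scores the reconstructed
laboratory-frame shapes against the withheld truth at selected instants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .datacube import DataCube
from .geometry import CapsuleMesh, predeform_ellipsoid
from .offline import ClusterPartition, OfflineConfig, run_offline
from .online import OnlineConfig, reconstruct_fields, run_online

__all__ = [
    "point_to_set_distance",
    "directed_mean_distance",
    "modified_hausdorff",
    "LOOReport",
    "loo_cross_validate",
]


def _as_points(F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[1] != 3 or F.shape[0] == 0:
        raise ValueError("expected a non-empty (N, 3) point set")
    if not np.all(np.isfinite(F)):
        raise ValueError("point set contains non-finite coordinates")
    return F


def point_to_set_distance(p: np.ndarray, G: np.ndarray) -> float:
    """Minimum Euclidean distance from point ``p`` to the set ``G``."""
    G = _as_points(G)
    return float(np.min(np.linalg.norm(G - np.asarray(p, dtype=float), axis=1)))


def directed_mean_distance(F: np.ndarray, G: np.ndarray) -> float:
    """Mean over ``F`` of the nearest-point distance to ``G``.

    Exact (no approximate nearest neighbors): a k-d tree accelerates the
    search but returns the same values as the brute-force double loop.
    """
    F, G = _as_points(F), _as_points(G)
    d, _ = cKDTree(G).query(F, k=1)
    return float(np.mean(d))


def modified_hausdorff(F: np.ndarray, G: np.ndarray) -> float:
    """``max(d_h(F, G), d_h(G, F))`` — symmetric, zero iff the directed
    mean distances both vanish, invariant under simultaneous rigid motion."""
    return max(directed_mean_distance(F, G), directed_mean_distance(G, F))


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------


@dataclass
class LOOReport:
    """Per-configuration, per-time normalized shape errors.

    ``table`` has one row per design point with columns ``ca``, ``beta``,
    ``boundary`` (edge-of-design flag) and one ``dmh_t{t}`` column per
    evaluation time holding ``d_MH / a``; failed configurations carry NaN
    and an entry in ``failures``.
    """

    table: pd.DataFrame
    eval_times: tuple[float, ...]
    failures: dict[int, str] = field(default_factory=dict)

    @property
    def error_columns(self) -> list[str]:
        return [f"dmh_t{t:g}" for t in self.eval_times]

    def summary(self) -> dict[str, float]:
        errs = self.table[self.error_columns]
        interior = errs[~self.table["boundary"]]
        boundary = errs[self.table["boundary"]]
        return {
            "mean": float(np.nanmean(errs.values)),
            "max": float(np.nanmax(errs.values)),
            "interior_mean": float(np.nanmean(interior.values)),
            "interior_max": float(np.nanmax(interior.values)),
            "boundary_mean": float(np.nanmean(boundary.values)),
            "boundary_max": float(np.nanmax(boundary.values)),
            "n_failures": float(len(self.failures)),
        }

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def heatmap_grid(self, t: float) -> pd.DataFrame:
        """Pivot of ``d_MH / a`` at one instant over the (Ca, beta) grid."""
        col = f"dmh_t{t:g}"
        return self.table.pivot_table(index="beta", columns="ca", values=col)

    def export_heatmaps(self, out_dir: str | Path, as_percent: bool = True) -> None:
        """Write one CSV grid and one rendered map per evaluation time."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for t in self.eval_times:
            grid = self.heatmap_grid(t)
            grid.to_csv(out_dir / f"heatmap_t{t:g}.csv")
            vals = grid.values * (100.0 if as_percent else 1.0)
            fig, ax = plt.subplots(figsize=(6, 4))
            im = ax.pcolormesh(
                grid.columns.values, grid.index.values, vals, shading="nearest"
            )
            label = "d_MH / a [%]" if as_percent else "d_MH / a"
            fig.colorbar(im, ax=ax, label=label)
            ax.set_xlabel("Ca")
            ax.set_ylabel("a/l")
            ax.set_title(f"shape error at t = {t:g}")
            fig.tight_layout()
            fig.savefig(out_dir / f"heatmap_t{t:g}.png", dpi=120)
            plt.close(fig)


def _positions(
    u_flat: np.ndarray, mesh: CapsuleMesh, beta: float
) -> np.ndarray:
    """Laboratory positions ``x = X_ref(beta) + u`` as an (Nx, 3) set."""
    ref = predeform_ellipsoid(mesh, beta).vertices
    return ref + u_flat.reshape(-1, 3)


def loo_cross_validate(
    cube: DataCube,
    mesh: CapsuleMesh,
    offline_config: OfflineConfig = OfflineConfig(),
    online_config: OnlineConfig = OnlineConfig(),
    eval_times: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0),
    partition: ClusterPartition | None = None,
    radius: float = 1.0,
) -> LOOReport:
    """Leave-one-out accuracy sweep over every design configuration.

    For each design point the offline model is rebuilt without it (within
    its cluster when a partition is given), the online stage is run at the
    withheld parameter, and the reconstructed laboratory-frame shape is
    compared to the withheld truth with ``d_MH / a`` at ``eval_times``
    (which must lie on the snapshot grid).  A failing configuration is
    recorded, not fatal.
    """
    eval_times = tuple(float(t) for t in eval_times)
    t_idx = {}
    for t in eval_times:
        hits = np.nonzero(np.abs(cube.times - t) < 1e-9)[0]
        if hits.size == 0:
            raise ValueError(f"evaluation time {t} is not a snapshot time")
        t_idx[t] = int(hits[0])

    rows = []
    failures: dict[int, str] = {}
    boundary_mask = cube.doe.boundary_mask()
    for j, theta in enumerate(cube.doe.points):
        row = {"ca": theta.ca, "beta": theta.beta, "boundary": bool(boundary_mask[j])}
        try:
            sub = cube.without_configuration(j)
            if partition is not None:
                from .offline import assign_cluster

                cid = assign_cluster(theta, partition, cube.doe)
                keep = partition.member_indices(sub.doe, cid)
                drop = [k for k in range(sub.nc) if k not in set(keep.tolist())]
                for k in sorted(drop, reverse=True):
                    sub = sub.without_configuration(k)
            bases = run_offline(sub, offline_config)
            cfg = online_config
            qm, traj = run_online(theta, bases, cfg)
            for t in eval_times:
                i_rom = traj.index_of(t)
                u_rom = reconstruct_fields(traj.alpha[:, i_rom], qm.phi_q)
                u_ref = cube.u[:, t_idx[t], j]
                d = modified_hausdorff(
                    _positions(u_rom, mesh, theta.beta),
                    _positions(u_ref, mesh, theta.beta),
                )
                row[f"dmh_t{t:g}"] = d / radius
        except Exception as exc:  # noqa: BLE001 - record and continue
            failures[j] = f"{type(exc).__name__}: {exc}"
            for t in eval_times:
                row.setdefault(f"dmh_t{t:g}", np.nan)
        rows.append(row)
    return LOOReport(
        table=pd.DataFrame(rows), eval_times=eval_times, failures=failures
    )
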