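"""The space-time-parameter datacube and its stacked-matrix rearrangements.

Nodal displacement and velocity fields are held as arrays of shape
``(3*Nx, Nt, Nc)``: space (node-major, (x, y, z) within node), time
(``t_i = i * dt``, ``i = 1..Nt``; the initial state ``u(0) = 0`` is implicit)
and parameter configuration.  Two rearrangements feed the offline POD stage:

* parametric stacking ``S`` of shape ``(3*Nx*Nt, Nc)`` — row block ``i``
  is the time-``t_i`` slice across configurations; its right singular
  vectors are the parametric modes;
* spatial stacking ``T`` of shape ``(3*Nx, Nt*Nc)`` — column block ``j``
  is configuration ``j`` across times; its left singular vectors are the
  spatial modes.

Databases persist as little-endian IEEE-754 double arrays (``u.bin``,
``v.bin``, C order) plus a JSON manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .params import DesignOfExperiment, ParameterPoint

__all__ = [
    "DataCube",
    "StackedMatrix",
    "stack_parametric",
    "stack_spatial",
    "unstack_parametric",
    "unstack_spatial",
    "save_cube",
    "load_cube",
    "datacube_scalar_count",
    "snapshot_count",
]

MANIFEST_VERSION = 1

FieldName = Literal["u", "v"]


def datacube_scalar_count(nx: int, nc: int, nt: int) -> int:
    """Number of stored double-precision scalars: 2 fields x 3 components."""
    return 2 * 3 * nx * nc * nt


def snapshot_count(dt: float, T: float) -> int:
    """Number of snapshot instants on ``(0, T]`` with spacing ``dt``."""
    nt = int(round(T / dt))
    if nt <= 0 or abs(nt * dt - T) > 1e-9 * max(T, dt):
        raise ValueError(f"T={T} is not a positive multiple of dt={dt}")
    return nt


@dataclass
class DataCube:
    """Nodal displacement/velocity snapshots over time and configurations."""

    u: np.ndarray  # (3*Nx, Nt, Nc)
    v: np.ndarray  # (3*Nx, Nt, Nc)
    times: np.ndarray  # (Nt,)
    doe: DesignOfExperiment
    mesh_ref: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have identical shapes")
        if self.u.ndim != 3:
            raise ValueError("fields must be (3*Nx, Nt, Nc) arrays")
        if self.u.shape[1] != len(self.times):
            raise ValueError("time axis does not match times vector")
        if self.u.shape[2] != self.doe.n_points:
            raise ValueError("configuration axis does not match the DOE")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 1e-9 * dt[0]):
            raise ValueError("times must be strictly increasing and uniform")

    @property
    def nx(self) -> int:
        return self.u.shape[0] // 3

    @property
    def nt(self) -> int:
        return self.u.shape[1]

    @property
    def nc(self) -> int:
        return self.u.shape[2]

    @property
    def dt(self) -> float:
        return float(self.times[0] if self.nt == 1 else self.times[1] - self.times[0])

    def field_array(self, name: FieldName) -> np.ndarray:
        if name not in ("u", "v"):
            raise ValueError(f"unknown field {name!r}")
        return self.u if name == "u" else self.v

    def scalar_count(self) -> int:
        return datacube_scalar_count(self.nx, self.nc, self.nt)

    def without_configuration(self, j: int) -> "DataCube":
        """A copy of the cube with configuration ``j`` removed."""
        keep = [k for k in range(self.nc) if k != j]
        doe = DesignOfExperiment(
            points=[self.doe.points[k] for k in keep],
            ca_step=self.doe.ca_step,
            beta_step=self.doe.beta_step,
            boundary=self.doe.boundary,
            cluster_labels=None
            if self.doe.cluster_labels is None
            else self.doe.cluster_labels[keep],
        )
        return DataCube(
            u=self.u[:, :, keep],
            v=self.v[:, :, keep],
            times=self.times,
            doe=doe,
            mesh_ref=self.mesh_ref,
            provenance=dict(self.provenance),
        )


@dataclass
class StackedMatrix:
    """A stacked rearrangement of one datacube field.

    ``kind='parametric'`` is the ``(3*Nx*Nt, Nc)`` stack whose SVD yields
    parameter modes; ``kind='spatial'`` is the ``(3*Nx, Nt*Nc)`` stack
    whose SVD yields spatial modes.
    """

    values: np.ndarray
    kind: Literal["parametric", "spatial"]
    field_name: FieldName
    nx: int
    nt: int
    nc: int

    def index_parametric(self, row: int, col: int) -> tuple[int, int, int, int]:
        """Map (row, col) of the parametric stack to (node, comp, time, cfg)."""
        i, r = divmod(row, 3 * self.nx)
        node, comp = divmod(r, 3)
        return node, comp, i, col

    def index_spatial(self, row: int, col: int) -> tuple[int, int, int, int]:
        """Map (row, col) of the spatial stack to (node, comp, time, cfg)."""
        node, comp = divmod(row, 3)
        j, i = divmod(col, self.nt)
        return node, comp, i, j


def stack_parametric(cube: DataCube, field_name: FieldName) -> StackedMatrix:
    """Stack time slices vertically: entry ``[i*3Nx + r, j]`` is the field
    component ``r`` at time ``t_{i+1}``, configuration ``j``."""
    arr = cube.field_array(field_name)
    values = np.ascontiguousarray(
        arr.transpose(1, 0, 2).reshape(3 * cube.nx * cube.nt, cube.nc)
    )
    return StackedMatrix(values, "parametric", field_name, cube.nx, cube.nt, cube.nc)


def stack_spatial(cube: DataCube, field_name: FieldName) -> StackedMatrix:
    """Gather configurations horizontally: column ``j*Nt + i`` is the field
    at time ``t_{i+1}``, configuration ``j``."""
    arr = cube.field_array(field_name)
    values = np.ascontiguousarray(
        arr.transpose(0, 2, 1).reshape(3 * cube.nx, cube.nt * cube.nc)
    )
    return StackedMatrix(values, "spatial", field_name, cube.nx, cube.nt, cube.nc)


def unstack_parametric(values: np.ndarray, nx: int, nt: int, nc: int) -> np.ndarray:
    """Inverse of :func:`stack_parametric`; returns a (3*Nx, Nt, Nc) array."""
    return values.reshape(nt, 3 * nx, nc).transpose(1, 0, 2)


def unstack_spatial(values: np.ndarray, nx: int, nt: int, nc: int) -> np.ndarray:
    """Inverse of :func:`stack_spatial`; returns a (3*Nx, Nt, Nc) array."""
    return values.reshape(3 * nx, nc, nt).transpose(0, 2, 1)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_cube(cube: DataCube, path: str | Path) -> None:
    """Persist a datacube as ``manifest.json`` + ``u.bin`` + ``v.bin``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": MANIFEST_VERSION,
        "nx": cube.nx,
        "nt": cube.nt,
        "nc": cube.nc,
        "times": cube.times.tolist(),
        "doe": {
            "points": cube.doe.as_array().tolist(),
            "ca_step": cube.doe.ca_step,
            "beta_step": cube.doe.beta_step,
            "cluster_labels": None
            if cube.doe.cluster_labels is None
            else np.asarray(cube.doe.cluster_labels).tolist(),
        },
        "mesh_ref": cube.mesh_ref,
        "provenance": cube.provenance,
        "dtype": "<f8",
        "order": "C",
        "component_layout": "node-major, (x, y, z) within node",
        "scalar_count": cube.scalar_count(),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    cube.u.astype("<f8").tofile(path / "u.bin")
    cube.v.astype("<f8").tofile(path / "v.bin")


def load_cube(path: str | Path) -> DataCube:
    """Load a datacube saved by :func:`save_cube`; fails loudly on damage."""
    path = Path(path)
    try:
        manifest = json.loads((path / "manifest.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot read datacube manifest in {path}: {exc}") from exc
    if manifest.get("version") != MANIFEST_VERSION:
        raise ValueError(
            f"unsupported datacube manifest version {manifest.get('version')!r}"
        )
    nx, nt, nc = manifest["nx"], manifest["nt"], manifest["nc"]
    shape = (3 * nx, nt, nc)
    expected = 3 * nx * nt * nc
    arrays = {}
    for name in ("u", "v"):
        data = np.fromfile(path / f"{name}.bin", dtype="<f8")
        if data.size != expected:
            raise ValueError(
                f"{name}.bin holds {data.size} doubles, expected {expected}"
            )
        arrays[name] = data.reshape(shape)
    doe_meta = manifest["doe"]
    doe = DesignOfExperiment(
        points=[ParameterPoint(ca, b) for ca, b in doe_meta["points"]],
        ca_step=doe_meta["ca_step"],
        beta_step=doe_meta["beta_step"],
        cluster_labels=None
        if doe_meta.get("cluster_labels") is None
        else np.asarray(doe_meta["cluster_labels"]),
    )
    return DataCube(
        u=arrays["u"],
        v=arrays["v"],
        times=np.asarray(manifest["times"], dtype=float),
        doe=doe,
        mesh_ref=manifest.get("mesh_ref", ""),
        provenance=manifest.get("provenance", {}),
    )
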