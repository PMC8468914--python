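"""Workflow orchestration: build-db -> offline -> query -> validate.

``run_all`` executes the four stages from one :class:`~capsrom.config.RunConfig`,
writing every artifact under an output directory together with a
machine-readable run manifest (configuration echo, seed, package versions,
SHA-256 hashes of the binary arrays, stage timings) so that re-runs are
bit-reproducible and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .datacube import DataCube, save_cube
from .geometry import write_mesh
from .metrics import loo_cross_validate
from .offline import GlobalBases, run_offline, save_bases
from .online import reconstruct_fields, run_online
from .params import ParameterPoint
from .surrogate import build_database, predeformed_reference

__all__ = ["run_all", "stage_build_db", "stage_offline", "stage_query", "stage_validate"]

logger = logging.getLogger("capsrom")


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_tree(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): _hash_file(p)
        for p in sorted(root.rglob("*"))
        if p.is_file() and p.suffix in (".bin", ".csv")
    }


def stage_build_db(config: RunConfig, out: Path) -> DataCube:
    mesh = config.mesh()
    doe = config.doe()
    cube = build_database(doe, mesh, config.dt, config.T, config.surrogate_params())
    save_cube(cube, out / "db")
    write_mesh(mesh, out / "db" / "mesh.ply")
    logger.info(
        "build-db: Nx=%d Nt=%d Nc=%d (%d stored doubles)",
        cube.nx, cube.nt, cube.nc, cube.scalar_count(),
    )
    return cube


def stage_offline(config: RunConfig, out: Path, cube: DataCube) -> GlobalBases:
    bases = run_offline(cube, config.offline_config())
    save_bases(bases, out / "model")
    logger.info("offline: ranks %s", bases.ranks)
    return bases


def stage_query(config: RunConfig, out: Path, bases: GlobalBases):
    theta_q = ParameterPoint(config.query_ca, config.query_beta)
    qm, traj = run_online(theta_q, bases, config.online_config())
    qdir = out / "query"
    qdir.mkdir(parents=True, exist_ok=True)
    header = (
        ["time"]
        + [f"alpha{k + 1}" for k in range(traj.alpha.shape[0])]
        + [f"xi{k + 1}" for k in range(traj.xi.shape[0])]
    )
    data = np.column_stack([traj.times, traj.alpha.T, traj.xi.T])
    np.savetxt(
        qdir / "trajectory.csv", data, delimiter=",",
        header=",".join(header), comments="",
    )
    # Export the reconstructed surface at each snapshot time as a VTK
    # legacy time series (plus the final state).
    from dataclasses import replace

    mesh = config.mesh()
    ref = predeformed_reference(mesh, theta_q)
    snap_every = max(1, int(round(config.dt / traj.dt_rom)))
    for k, i in enumerate(range(0, len(traj.times), snap_every)):
        u_i = reconstruct_fields(traj.alpha[:, i], qm.phi_q)
        shape = replace(ref, vertices=ref.vertices + u_i.reshape(-1, 3))
        write_mesh(shape, qdir / f"shape_{k:04d}.vtk")
    u_final = reconstruct_fields(traj.alpha[:, -1], qm.phi_q)
    shape = replace(ref, vertices=ref.vertices + u_final.reshape(-1, 3))
    write_mesh(shape, qdir / "shape_final.vtk")
    logger.info(
        "query: theta=(%.3g, %.3g), %d ROM steps", theta_q.ca, theta_q.beta,
        len(traj.times) - 1,
    )
    return qm, traj


def stage_validate(config: RunConfig, out: Path, cube: DataCube):
    report = loo_cross_validate(
        cube,
        config.mesh(),
        offline_config=config.offline_config(),
        online_config=config.online_config(),
        eval_times=tuple(config.eval_times),
        partition=config.partition(),
        radius=config.mesh_radius,
    )
    rdir = out / "report"
    rdir.mkdir(parents=True, exist_ok=True)
    report.to_csv(rdir / "loo.csv")
    report.export_heatmaps(rdir)
    (rdir / "summary.json").write_text(json.dumps(report.summary(), indent=2))
    logger.info("validate: %s", report.summary())
    return report


def run_all(config: RunConfig, out: str | Path, dry_run: bool = False) -> dict:
    """Execute all four stages; returns the run manifest."""
    out = Path(out)
    plan = ["build-db", "offline", "query", "validate"]
    if dry_run:
        manifest = {"plan": plan, "out": str(out), "config": _config_echo(config)}
        print(json.dumps(manifest, indent=2))
        return manifest
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    timings: dict[str, float] = {}
    results: dict = {}
    stages = {
        "build-db": lambda: stage_build_db(config, out),
        "offline": lambda: stage_offline(config, out, results["build-db"]),
        "query": lambda: stage_query(config, out, results["offline"]),
        "validate": lambda: stage_validate(config, out, results["build-db"]),
    }
    for name in plan:
        t0 = time.perf_counter()
        try:
            results[name] = stages[name]()
        except Exception as exc:
            logger.error("stage %s failed: %s", name, exc)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
    manifest = {
        "capsrom_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "timings_s": timings,
        "hashes": _hash_tree(out),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _config_echo(config: RunConfig) -> dict:
    import dataclasses

    return {
        f.name: getattr(config, f.name)
        for f in dataclasses.fields(config)
        if not f.name.startswith("_")
    }


def _setup_logging(out: Path) -> None:
    logger.setLevel(logging.INFO)
    have = {type(h) for h in logger.handlers}
    if logging.StreamHandler not in have:
        sh = logging.StreamHandler(sys.stderr)
        sh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(sh)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
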