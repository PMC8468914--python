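"""Run configuration: a single TOML file driving the whole workflow.

Every tunable of the four stages (database generation, offline reduction,
online query, validation) lives here with its default.  Defaults marked
"reference" reproduce the reference study settings (snapshot step 0.2 up to
time 20, Cartesian design steps 0.01/0.05, global ranks 40/40/50/50,
second-order DA with 12 neighbors and anisotropy 1.9, local ranks 10/10,
temporal window twice the snapshot step); the rest are artifact defaults
documented in docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .diffuse import DAConfig
from .geometry import CapsuleMesh, subdivide_icosphere
from .offline import ClusterPartition, OfflineConfig
from .online import OnlineConfig
from .params import DesignOfExperiment, build_doe
from .surrogate import SurrogateParams

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    # [mesh]
    mesh_level: int = 4
    mesh_radius: float = 1.0
    # [doe]
    ca_step: float = 0.01
    beta_step: float = 0.05
    extra_ca: list[float] = field(default_factory=lambda: [0.005])
    # [time]
    dt: float = 0.2
    T: float = 20.0
    # [surrogate]
    q0: float = 1.2
    tau0: float = 0.8
    parachute_gain: float = 0.35
    translation_speed: float | None = None
    noise_sd: float = 0.0
    seed: int = 0
    # [offline]
    k_u_x: int = 40
    k_u_c: int = 40
    k_v_x: int = 50
    k_v_c: int = 50
    offline_tol: float | None = None
    # [clusters]
    n_clusters: int = 1
    ca_split: float = 0.10
    overlap: float = 0.02
    # [online]
    da_order: int = 2
    neighbor_count: int = 12
    r_tilde: float = 1.9
    mu: int = 10
    mv: int = 10
    local_tol: float | None = None
    dt_rom: float | None = None
    temporal_window: float | None = None
    t_final: float | None = None
    # [query]
    query_ca: float = 0.10
    query_beta: float = 0.90
    # [validation]
    eval_times: list[float] = field(default_factory=lambda: [1.0, 2.0, 4.0, 8.0])

    _SECTIONS = {
        "mesh": ("mesh_level", "mesh_radius"),
        "doe": ("ca_step", "beta_step", "extra_ca"),
        "time": ("dt", "T"),
        "surrogate": (
            "q0", "tau0", "parachute_gain", "translation_speed",
            "noise_sd", "seed",
        ),
        "offline": ("k_u_x", "k_u_c", "k_v_x", "k_v_c", "offline_tol"),
        "clusters": ("n_clusters", "ca_split", "overlap"),
        "online": (
            "da_order", "neighbor_count", "r_tilde", "mu", "mv",
            "local_tol", "dt_rom", "temporal_window", "t_final",
        ),
        "query": ("query_ca", "query_beta"),
        "validation": ("eval_times",),
    }

    _SECTION_KEYS = {
        "mesh_level": "level",
        "mesh_radius": "radius",
        "offline_tol": "tol",
        "query_ca": "ca",
        "query_beta": "beta",
    }

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        try:
            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        except (OSError, tomllib.TOMLDecodeError) as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        kwargs: dict[str, Any] = {}
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        for section, names in cls._SECTIONS.items():
            table = raw.pop(section, {})
            if not isinstance(table, dict):
                raise ConfigError(f"section [{section}] must be a table")
            for name in names:
                key = cls._SECTION_KEYS.get(name, name)
                if key in table:
                    kwargs[name] = table.pop(key)
            if table:
                raise ConfigError(
                    f"unknown key(s) in [{section}]: {sorted(table)}"
                )
        if raw:
            raise ConfigError(f"unknown section(s): {sorted(raw)}")
        try:
            cfg = cls(**{k: v for k, v in kwargs.items() if k in known})
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    def to_toml(self, path: str | Path) -> None:
        lines: list[str] = []
        for section, names in self._SECTIONS.items():
            body = []
            for name in names:
                value = getattr(self, name)
                if value is None:
                    continue  # optional keys are omitted when unset
                key = self._SECTION_KEYS.get(name, name)
                body.append(f"{key} = {_toml_value(value)}")
            if body:
                lines.append(f"[{section}]")
                lines.extend(body)
                lines.append("")
        Path(path).write_text("\n".join(lines))

    def validate(self) -> None:
        if self.dt <= 0 or self.T <= 0:
            raise ConfigError("dt and T must be positive")
        if self.mesh_level < 0 or self.mesh_level > 7:
            raise ConfigError("mesh level must lie in [0, 7]")
        if self.n_clusters not in (1, 2):
            raise ConfigError("n_clusters must be 1 or 2")
        if self.da_order not in (1, 2):
            raise ConfigError("da_order must be 1 or 2")

    # -- factories ----------------------------------------------------------

    def mesh(self) -> CapsuleMesh:
        return subdivide_icosphere(self.mesh_level, self.mesh_radius)

    def doe(self) -> DesignOfExperiment:
        return build_doe(
            ca_step=self.ca_step,
            beta_step=self.beta_step,
            extra_ca=tuple(self.extra_ca),
        )

    def surrogate_params(self) -> SurrogateParams:
        return SurrogateParams(
            q0=self.q0,
            tau0=self.tau0,
            parachute_gain=self.parachute_gain,
            translation_speed=self.translation_speed,
            seed=self.seed,
            noise_sd=self.noise_sd,
        )

    def offline_config(self) -> OfflineConfig:
        return OfflineConfig(
            k_u_x=self.k_u_x,
            k_u_c=self.k_u_c,
            k_v_x=self.k_v_x,
            k_v_c=self.k_v_c,
            tol=self.offline_tol,
        )

    def online_config(self) -> OnlineConfig:
        return OnlineConfig(
            da=DAConfig(
                order=self.da_order,
                neighbor_count=self.neighbor_count,
                r_tilde=self.r_tilde,
            ),
            mu=self.mu,
            mv=self.mv,
            local_tol=self.local_tol,
            dt_rom=self.dt_rom,
            temporal_window=self.temporal_window,
            t_final=self.t_final,
        )

    def partition(self) -> ClusterPartition | None:
        if self.n_clusters == 1:
            return None
        return ClusterPartition(
            ca_split=self.ca_split, overlap=self.overlap, n_clusters=2
        )


def _toml_value(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise ConfigError(f"cannot serialize config value {value!r}")
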