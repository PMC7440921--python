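"""Run configuration: schema-validated loading, serialisation, outputs.

Configs are flat TOML (primary) or YAML documents with three tables --
``lifecycle``, ``traits`` (``red`` / ``blue`` sub-tables) and ``mutation``
-- plus top-level ``scenario``, ``seed``, ``scale_D``, ``scale_M``. Unknown
keys are rejected and every numeric field is range-checked. Outputs are CSV
tables plus a JSON metadata record; config + seed regenerate every table
bit-identically.
"""

from __future__ import annotations

import json
import time
import tomllib
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import __version__
from .experiments import SCENARIOS, ScenarioConfig
from .lifecycle import LifeCycleParams, MutationKernel, Trajectory
from .particles import ParticleType


class ConfigError(ValueError):
    """A configuration file failed parsing or validation."""


class TraitSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    r: float = Field(gt=0)
    a_intra: float = Field(ge=0)
    a_inter: float = Field(ge=0)


class TraitsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    red: TraitSection
    blue: TraitSection


class LifecycleSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    D: int = Field(ge=1)
    B: int = Field(ge=1)
    T: float = Field(ge=0)
    rho: float = Field(ge=0, lt=1)
    phi_hat: float = Field(gt=0, lt=1)
    M: int = Field(ge=0)
    regime: Literal["neutral", "selective"]


class MutationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    traits: list[Literal["r", "a_inter"]] = []
    sigma: float = Field(default=0.05, ge=0)


class RunConfig(BaseModel):
    """Validated, self-describing run configuration."""

    model_config = ConfigDict(extra="forbid")

    scenario: Literal[SCENARIOS] = "full_evolution"
    seed: int = 0
    scale_D: float = Field(default=1.0, gt=0)
    scale_M: float = Field(default=1.0, ge=0)
    replicates: int = Field(default=50, ge=2)
    initial_colour: Optional[float] = Field(default=None, ge=0, le=1)
    lifecycle: LifecycleSection
    traits: TraitsSection
    mutation: MutationSection = MutationSection()

    @model_validator(mode="after")
    def _check_extinction_count(self) -> "RunConfig":
        lc = self.lifecycle
        if lc.rho > 0 and int(np.rint(lc.rho * lc.D)) < 1:
            raise ValueError("lifecycle: round(rho * D) must be >= 1 when rho > 0")
        return self

    # -- conversions -------------------------------------------------------
    def lifecycle_params(self) -> LifeCycleParams:
        lc = self.lifecycle
        return LifeCycleParams(D=lc.D, B=lc.B, T=lc.T, rho=lc.rho,
                               phi_hat=lc.phi_hat, M=lc.M, regime=lc.regime)

    def kernel(self) -> MutationKernel:
        return MutationKernel(traits=frozenset(self.mutation.traits),
                              sigma=self.mutation.sigma)

    def particle_types(self) -> tuple[ParticleType, ParticleType]:
        red = ParticleType(colour="red", **self.traits.red.model_dump())
        blue = ParticleType(colour="blue", **self.traits.blue.model_dump())
        return red, blue

    def scenario_config(self) -> ScenarioConfig:
        red, blue = self.particle_types()
        return ScenarioConfig(
            scenario=self.scenario,
            params=self.lifecycle_params(),
            kernel=self.kernel(),
            red=red,
            blue=blue,
            seed=self.seed,
            scale_D=self.scale_D,
            scale_M=self.scale_M,
            replicates=self.replicates,
            initial_colour=self.initial_colour,
        )


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML or YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(path.read_text())
        else:
            data = tomllib.loads(path.read_text())
    except (tomllib.TOMLDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"{path}: parse error: {exc}") from exc
    return validate_config(data, source=str(path))


def validate_config(data: dict, source: str = "<dict>") -> RunConfig:
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"{source}: invalid config: {details}") from exc


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, list):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialise {v!r}")


def dumps_toml(config: RunConfig) -> str:
    """Serialise a RunConfig to TOML (round-trips through load_config)."""
    data = config.model_dump(exclude_none=True)
    lines = []
    tables = {k: v for k, v in data.items() if isinstance(v, dict)}
    for k, v in data.items():
        if not isinstance(v, dict):
            lines.append(f"{k} = {_toml_value(v)}")

    def emit(name: str, tbl: dict) -> None:
        lines.append("")
        lines.append(f"[{name}]")
        for k, v in tbl.items():
            if isinstance(v, dict):
                continue
            lines.append(f"{k} = {_toml_value(v)}")
        for k, v in tbl.items():
            if isinstance(v, dict):
                emit(f"{name}.{k}", v)

    for name, tbl in tables.items():
        emit(name, tbl)
    return "\n".join(lines) + "\n"


def write_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(dumps_toml(config))
    return path


def write_outputs(
    traj: Trajectory,
    summary: pd.DataFrame,
    config: RunConfig,
    outdir: str | Path,
    extra_tables: dict[str, pd.DataFrame] | None = None,
) -> dict[str, Path]:
    """Write trajectory, summary, metadata and log into ``outdir``.

    ``trajectory.csv`` has one row per (generation, collective) with the
    adult colour; ``summary.csv`` one row per generation; ``metadata.json``
    the full config, seed, package version, run status and wall-clock time;
    ``run.log`` an append-only line per invocation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    colours = traj.colours_matrix()
    long = pd.DataFrame({
        "generation": np.repeat([r.generation for r in traj.records], traj.final.D),
        "collective": np.tile(np.arange(traj.final.D), len(traj.records)),
        "adult_colour": colours.ravel() if colours.size else np.empty(0),
    })
    paths["trajectory"] = outdir / "trajectory.csv"
    long.to_csv(paths["trajectory"], index=False)

    paths["summary"] = outdir / "summary.csv"
    summary.to_csv(paths["summary"], index=False)

    for name, table in (extra_tables or {}).items():
        p = outdir / f"{name}.csv"
        table.to_csv(p, index=False)
        paths[name] = p

    meta = {
        "config": config.model_dump(exclude_none=True),
        "seed": traj.seed,
        "version": __version__,
        "status": traj.status,
        "n_generations": traj.n_generations,
        "written_at_unix": time.time(),
        "schema": {
            "trajectory": list(long.columns),
            "summary": list(summary.columns),
        },
    }
    paths["metadata"] = outdir / "metadata.json"
    paths["metadata"].write_text(json.dumps(meta, indent=2, sort_keys=True))

    logline = (
        f"{time.strftime('%Y-%m-%dT%H:%M:%S')} scenario={config.scenario} "
        f"seed={traj.seed} generations={traj.n_generations} status={traj.status}\n"
    )
    logpath = outdir / "run.log"
    with logpath.open("a") as fh:
        fh.write(logline)
    paths["log"] = logpath
    return paths
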