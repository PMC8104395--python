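"""Run configuration: TOML schema, validation, and the packaged defaults.

A run configuration holds every model constant (lattice dimensions, DoG
filter, local projection table, long-range profiles, ambient drives, the
6E->4E control weight, the rate-dependent multipliers), the stimulus block and
solver settings.  The packaged ``table1_defaults.toml`` carries the standard
local-circuit parameterization together with the frozen calibrated long-range
and ambient defaults; ``reduced_3x3.toml`` / ``reduced_5x5.toml`` are small
lattices for tests and oracle comparisons.
"""

from __future__ import annotations

import tomllib
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .geometry import Lattice, build_lattice
from .lgn import DEFAULT_RADIUS_GRID, DoGKernelParams
from .params import (
    LongRangeProfile,
    ModelParameters,
    NonlinearMultiplier,
    ProjectionSpec,
    _TABLE_LOCAL,
)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LatticeBlock(_Strict):
    n_hc_per_side: int = 17
    groups_per_hc_side: int = 7
    hc_size: float = 0.25


class DoGBlock(_Strict):
    shape: float = 4.1
    r_in: float = 0.1
    r_out: float = 0.31
    z_norm: float = 3.62283


class ProjectionBlock(_Strict):
    weight: float | None = None  # None only for the 6E->4E control entry
    sigma: float
    cutoff: float


class LongRangeBlock(_Strict):
    pe: list[list[float]]
    pi: list[list[float]]

    @field_validator("pe", "pi")
    @classmethod
    def _pairs(cls, v):
        if any(len(k) != 2 for k in v):
            raise ValueError("long-range knots must be [distance, value] pairs")
        return v


class ControlBlock(_Strict):
    w_6e4e: float = Field(gt=0)


class MultiplierBlock(_Strict):
    projection: str
    eta_th: float
    kappa: float
    m_max: float = 2.0


class NonlinearBlock(_Strict):
    enabled: bool = False
    multipliers: list[MultiplierBlock] = []


class StimulusBlock(_Strict):
    theta0: float = 90.0
    radii: list[float] | Literal["default"] = "default"

    def radius_grid(self) -> np.ndarray:
        if self.radii == "default":
            return DEFAULT_RADIUS_GRID.copy()
        return np.asarray(self.radii, dtype=float)


class SolverBlock(_Strict):
    tol: float = 1e-10
    nonlinear_tol: float = 1e-8
    damping: float = 0.5
    max_iter: int = 500


class OutputBlock(_Strict):
    formats: list[str] = ["csv"]
    png: bool = False


class RunConfig(_Strict):
    lattice: LatticeBlock = LatticeBlock()
    dog: DoGBlock = DoGBlock()
    projections: dict[str, ProjectionBlock]
    control: ControlBlock
    longrange: LongRangeBlock
    ambient: dict[str, float]
    nonlinear: NonlinearBlock = NonlinearBlock()
    stimulus: StimulusBlock = StimulusBlock()
    solver: SolverBlock = SolverBlock()
    output: OutputBlock = OutputBlock()

    @model_validator(mode="after")
    def _check(self):
        expected = {f"{s}->{t}" for s, t in _TABLE_LOCAL}
        got = set(self.projections)
        if got != expected:
            raise ValueError(f"projection table mismatch: {sorted(got ^ expected)}")
        # delegate constraint checking (endpoints, ranges) to the domain types
        self.to_model_parameters()
        return self

    def to_lattice(self) -> Lattice:
        return build_lattice(
            self.lattice.n_hc_per_side,
            self.lattice.groups_per_hc_side,
            self.lattice.hc_size,
        )

    def to_dog_params(self) -> DoGKernelParams:
        d = self.dog
        return DoGKernelParams(d.shape, d.r_in, d.r_out, d.z_norm)

    def to_model_parameters(self) -> ModelParameters:
        projections = {}
        for key, blk in self.projections.items():
            src, tgt = key.split("->")
            w = self.control.w_6e4e if blk.weight is None else blk.weight
            projections[(src, tgt)] = ProjectionSpec(src, tgt, w, blk.sigma, blk.cutoff)
        longrange = LongRangeProfile(
            pe_knots=tuple((d, v) for d, v in self.longrange.pe),
            pi_knots=tuple((d, v) for d, v in self.longrange.pi),
        )
        multipliers = tuple(
            NonlinearMultiplier(
                projection=tuple(m.projection.split("->")),
                eta_th=m.eta_th, kappa=m.kappa, m_max=m.m_max,
            )
            for m in self.nonlinear.multipliers
        )
        return ModelParameters(
            projections=projections,
            longrange=longrange,
            ambient=dict(self.ambient),
            w_6e4e=self.control.w_6e4e,
            multipliers=multipliers,
            nonlinear=self.nonlinear.enabled,
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML run configuration."""
    with open(path, "rb") as f:
        raw = tomllib.load(f)
    return RunConfig.model_validate(raw)


def load_default_config(name: str = "table1_defaults") -> RunConfig:
    """Load one of the packaged configurations
    (table1_defaults, reduced_3x3, reduced_5x5).

    The reduced configurations override only the lattice block; all circuit
    parameters come from the packaged defaults."""
    base = tomllib.loads(
        resources.files("v1surround.data").joinpath("table1_defaults.toml").read_text()
    )
    if name != "table1_defaults":
        overlay = tomllib.loads(
            resources.files("v1surround.data").joinpath(f"{name}.toml").read_text()
        )
        base.update(overlay)
    return RunConfig.model_validate(base)


def default_parameters() -> ModelParameters:
    """The frozen packaged default parameter set."""
    return load_default_config().to_model_parameters()


# ---------------------------------------------------------------------------
# canonical TOML serialization (round-trips byte-identically)

def _fmt(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    if isinstance(v, int):
        return str(v)
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_fmt(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)}")


def _quote_key(k: str) -> str:
    if k.replace("_", "").replace("-", "").isalnum() and "->" not in k:
        return k
    return f'"{k}"'


def dumps_config(config: RunConfig) -> str:
    """Serialize a RunConfig to canonical TOML."""
    data = config.model_dump()
    lines: list[str] = []
    for section in ("lattice", "dog", "control", "ambient", "longrange",
                    "stimulus", "solver", "output"):
        lines.append(f"[{section}]")
        for k, v in data[section].items():
            lines.append(f"{_quote_key(k)} = {_fmt(v)}")
        lines.append("")
    for key, blk in data["projections"].items():
        lines.append(f'[projections."{key}"]')
        for k, v in blk.items():
            if v is None:
                continue  # the control-weight entry stays implicit
            lines.append(f"{k} = {_fmt(v)}")
        lines.append("")
    lines.append("[nonlinear]")
    lines.append(f"enabled = {_fmt(data['nonlinear']['enabled'])}")
    lines.append("")
    for m in data["nonlinear"]["multipliers"]:
        lines.append("[[nonlinear.multipliers]]")
        for k, v in m.items():
            lines.append(f"{k} = {_fmt(v)}")
        lines.append("")
    return "\n".join(lines)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(dumps_config(config))
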