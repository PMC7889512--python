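"""Run configuration: defaults, YAML round-trip, strict validation.

Every key defaults to the core model value, so an empty config file
reproduces the baseline simulation; unknown keys are rejected rather
than silently ignored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .leafgeom import PAPER_ANGLES
from .solver import SolverSettings
from .transport import ModelParams

__all__ = ["RunConfig", "load_config"]

#: named angle vocabularies for sweeps; `paper13` hard-codes the 13-angle
#: grid so sweeps cannot drift from the published sampling
ANGLE_SETS = {"paper13": list(PAPER_ANGLES)}


@dataclass
class ShapeConfig:
    variant: str = "reference"
    spacing_mm: float = 2.0


@dataclass
class VeinConfig:
    theta_deg: float = 0.0
    mode: str = "constant_total_length"
    Lv_mm: float = 10.0
    order45_parity: str = "even4"


@dataclass
class ParamConfig:
    E: float = -2.00
    Lambda: float = 2.78e-7
    loading_gradient: bool = False
    K_c: float = 0.50
    p_petiole_xyl: float = 0.00
    p_petiole_ph: float = 0.20
    T: float = 293.0
    sucrose_scheme: str = "literal"
    k2_multiplier: float = 1.0
    conductivity: dict = field(default_factory=dict)   # per-order overrides


@dataclass
class SolverConfig:
    tol: float = 1e-10
    max_iter: int = 60
    seed: int = 0


@dataclass
class ExperimentConfig:
    angles: object = "paper13"        # named set or explicit list
    shapes: object = "reference"      # variant name, list, or "all"


@dataclass
class RunConfig:
    shape: ShapeConfig = field(default_factory=ShapeConfig)
    veins: VeinConfig = field(default_factory=VeinConfig)
    params: ParamConfig = field(default_factory=ParamConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    output_dir: str = "runs"

    def model_params(self) -> ModelParams:
        p = self.params
        mp = ModelParams(
            E=p.E,
            Lambda=p.Lambda,
            loading_gradient=p.loading_gradient,
            K_c=p.K_c,
            p_petiole_xyl=p.p_petiole_xyl,
            p_petiole_ph=p.p_petiole_ph,
            T=p.T,
            sucrose_scheme=p.sucrose_scheme,
        )
        for order, value in p.conductivity.items():
            mp = mp.with_conductivity(int(order), float(value))
        if p.k2_multiplier != 1.0:
            mp = mp.with_conductivity(2, mp.conductivity[2] * p.k2_multiplier)
        return mp

    def solver_settings(self) -> SolverSettings:
        return SolverSettings(tol=self.solver.tol, max_iter=self.solver.max_iter,
                              seed=self.solver.seed)

    def angle_list(self) -> list:
        a = self.experiment.angles
        if isinstance(a, str):
            try:
                return list(ANGLE_SETS[a])
            except KeyError:
                raise ValueError(f"unknown angle set {a!r}; known: {sorted(ANGLE_SETS)}")
        return [float(x) for x in a]

    def shape_list(self) -> list:
        s = self.experiment.shapes
        if s == "all":
            return ["wide", "reference", "narrow"]
        if isinstance(s, str):
            return [s]
        return list(s)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _build_section(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    return cls(**data)


def load_config(source) -> RunConfig:
    """Load a RunConfig from a YAML file path, YAML text, or dict."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        data = yaml.safe_load(Path(source).read_text()) or {}
    elif isinstance(source, str):
        data = yaml.safe_load(source) or {}
    else:
        data = dict(source or {})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    section_types = {
        "shape": ShapeConfig,
        "veins": VeinConfig,
        "params": ParamConfig,
        "solver": SolverConfig,
        "experiment": ExperimentConfig,
    }
    sections = {}
    for name, cls in section_types.items():
        if name in data:
            sections[name] = _build_section(cls, data[name] or {}, name)
    cfg = RunConfig(**sections)
    if "output_dir" in data:
        cfg.output_dir = str(data["output_dir"])
    return cfg
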