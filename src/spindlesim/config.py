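"""Run configuration: nested dataclasses with YAML round-trip.

Units in config files: speeds nm/s, rates 1/s, lengths um, forces pN,
kT pN nm, viscosity Pa s, diffusion um^2/s, lattice step nm, times s.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .dynamic_filaments import DynamicInstabilityParams, NucleationSource
from .mechanics import ConfinementGeometry, SimulationConstants, StericParams
from .motors import CrosslinkComplex, MotorUnitSpec, UnitKind, make_archetype

__all__ = ["MechanicsParams", "MotorBlock", "SimulationConfig"]


@dataclass(frozen=True)
class MechanicsParams:
    rigidity: float = 20.0  # pN um^2, flexural rigidity kappa
    segmentation: float = 0.5  # um
    steric: StericParams = field(default_factory=StericParams)
    drag_factor: float = 1.0  # geometric factor in gamma = 3 pi eta s * c
    free_diffusion: float = 10.0  # um^2/s, unbound complex diffusion
    removal_length: float = 0.005  # um, complete-shrinkage threshold
    cg_rtol: float = 3e-3  # implicit-solve residual tolerance
    cg_maxiter: int = 16  # implicit-solve iteration cap


@dataclass(frozen=True)
class MotorBlock:
    species: CrosslinkComplex
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("motor count must be >= 0")


@dataclass
class SimulationConfig:
    constants: SimulationConstants = field(default_factory=SimulationConstants)
    geometry: ConfinementGeometry = field(default_factory=ConfinementGeometry)
    dynamics: DynamicInstabilityParams = field(
        default_factory=lambda: DynamicInstabilityParams(30.0, 375.0, 0.012, 0.0)
    )
    nucleation: NucleationSource = field(default_factory=lambda: NucleationSource(4.0))
    motors: list = field(default_factory=list)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    duration: float = 1980.0  # s (33 min)
    frame_interval: float = 1.98  # s (1000 frames over 33 min)
    seed: int = 0
    name: str = "run"

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                d = {}
                for f in dataclasses.fields(obj):
                    d[f.name] = enc(getattr(obj, f.name))
                if isinstance(obj, UnitKind):
                    return obj.name
                return d
            if isinstance(obj, UnitKind):
                return obj.name
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, list):
                return [enc(x) for x in obj]
            return obj

        return enc(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        out = cls()
        if "constants" in data:
            out.constants = SimulationConstants(**data["constants"])
        if "geometry" in data:
            g = dict(data["geometry"])
            g["dims"] = tuple(g.get("dims", (30.0, 30.0, 0.2)))
            out.geometry = ConfinementGeometry(**g)
        if "dynamics" in data:
            out.dynamics = DynamicInstabilityParams(**data["dynamics"])
        if "nucleation" in data:
            n = dict(data["nucleation"])
            for key in ("volume", "center"):
                if key in n:
                    n[key] = tuple(n[key])
            out.nucleation = NucleationSource(**n)
        if "mechanics" in data:
            m = dict(data["mechanics"])
            if "steric" in m:
                m["steric"] = StericParams(**m["steric"])
            out.mechanics = MechanicsParams(**m)
        if "motors" in data:
            out.motors = [_motor_block_from_dict(b) for b in data["motors"]]
        for key in ("duration", "frame_interval", "seed", "name"):
            if key in data:
                setattr(out, key, data[key])
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))


def _unit_from_dict(d: dict) -> MotorUnitSpec:
    d = dict(d)
    d["kind"] = UnitKind[d["kind"]] if isinstance(d.get("kind"), str) else d["kind"]
    return MotorUnitSpec(**d)


def _motor_block_from_dict(d: dict) -> MotorBlock:
    d = dict(d)
    count = int(d.pop("count", 0))
    if "archetype" in d:
        name = d.pop("archetype")
        minus_speed = d.pop("minus_speed", 30.0)
        overrides = {}
        for key in ("rest_length", "stiffness", "k_on", "binding_range", "parallel_only"):
            if key in d:
                overrides[key] = d.pop(key)
        for slot in ("unit_a", "unit_b"):
            if slot in d:
                overrides[slot] = _unit_from_dict(d.pop(slot))
        species = make_archetype(name, minus_speed=minus_speed, **overrides)
    else:
        spec = dict(d.pop("species"))
        spec["unit_a"] = _unit_from_dict(spec["unit_a"])
        spec["unit_b"] = _unit_from_dict(spec["unit_b"])
        species = CrosslinkComplex(**spec)
    return MotorBlock(species=species, count=count)
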