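"""Pipeline configuration: nested sections mirroring each module.

Loaded from YAML; unknown keys are rejected so typos fail loudly, and a
round trip through ``to_dict``/``from_dict`` is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields

import yaml

from .errors import ConfigurationError
from .sensor_sim import SimConfig


def _from_mapping(cls, d: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(d) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**d)


@dataclass(frozen=True)
class DdftConfig:
    K_max: int = 6
    eps: float = 0.05           # slope-stability threshold (relative)
    n_init: int = 5
    grid_resolution: int = 200
    grid_padding: float = 0.10

    def __post_init__(self) -> None:
        if self.K_max < 2 or self.eps <= 0:
            raise ConfigurationError("K_max >= 2 and eps > 0 required")


@dataclass(frozen=True)
class FallMapConfig:
    projection: tuple[str, str] = ("z", "speed")
    sd_multiplier: float = 1.5
    shutoff_delay: float = 5.0

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0 or self.shutoff_delay < 0:
            raise ConfigurationError("sd_multiplier > 0 and shutoff_delay >= 0")


@dataclass(frozen=True)
class EvalConfig:
    k: int = 10
    repeated_cv: bool = False
    repetitions: int = 10
    test_events_per_rep: int = 10

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigurationError("k must be >= 2")


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    ddft: DdftConfig = field(default_factory=DdftConfig)
    fallmap: FallMapConfig = field(default_factory=FallMapConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["stage_fractions"] = list(self.sim.stage_fractions)
        d["fallmap"]["projection"] = list(self.fallmap.projection)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sections = {}
        for name, sub_cls in [("sim", SimConfig), ("ddft", DdftConfig),
                              ("fallmap", FallMapConfig), ("eval", EvalConfig)]:
            sub = dict(d.pop(name, {}))
            if name == "sim" and "stage_fractions" in sub:
                sub["stage_fractions"] = tuple(sub["stage_fractions"])
            if name == "fallmap" and "projection" in sub:
                sub["projection"] = tuple(sub["projection"])
            sections[name] = _from_mapping(sub_cls, sub)
        top = {f.name: d.pop(f.name) for f in fields(cls)
               if f.name in d and f.name not in sections}
        if d:
            raise ConfigurationError(f"unknown top-level keys: {sorted(d)}")
        return cls(**sections, **top)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config file must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
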