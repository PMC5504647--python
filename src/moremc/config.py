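"""Run configuration: sampler + mover settings, round-tripped through YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .moves import MoveConfig
from .samplers import SamplerConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a sampling run (paths excluded)."""

    method: str = "hmo-remc"
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    moves: MoveConfig = field(default_factory=MoveConfig)
    weights_preset: str = "hard"

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "sampler": asdict(self.sampler),
            "moves": asdict(self.moves),
            "weights_preset": self.weights_preset,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(
            method=data.get("method", "hmo-remc"),
            sampler=SamplerConfig(**data.get("sampler", {})),
            moves=MoveConfig(**data.get("moves", {})),
            weights_preset=data.get("weights_preset", "hard"),
        )

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, sampler=replace(self.sampler, seed=seed))


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
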