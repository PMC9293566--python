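"""Run configuration: one YAML document covering network, training,
loss weights and evaluation options, round-tripping losslessly."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .backbone import LossWeights, NetworkConfig, TrainConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    loss_weights: LossWeights = field(default_factory=LossWeights)
    variant: str = "sideout"
    threshold: float = 0.5
    use_fov: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["network"]["transformer_levels"] = list(self.network.transformer_levels)
        d["loss_weights"]["alpha"] = list(self.loss_weights.alpha)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        net = dict(d.get("network", {}))
        if "transformer_levels" in net:
            net["transformer_levels"] = tuple(net["transformer_levels"])
        lw = dict(d.get("loss_weights", {}))
        if "alpha" in lw:
            lw["alpha"] = tuple(lw["alpha"])
        return cls(
            network=NetworkConfig(**net),
            training=TrainConfig(**d.get("training", {})),
            loss_weights=LossWeights(**lw),
            variant=d.get("variant", "sideout"),
            threshold=float(d.get("threshold", 0.5)),
            use_fov=bool(d.get("use_fov", False)),
        )

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
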