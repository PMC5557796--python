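"""Run configuration: every tunable threshold in one serializable object.

The resolved configuration (and package version) is written verbatim
into every output directory so a run can be reproduced from its outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import DataError
from .interactions import InteractionConfig

__all__ = ["RunConfig"]

_BOUNDS = {
    "pocket_radius": (0.0, 15.0),
    "r2_threshold": (0.0, 1.0),
    "delta_threshold": (0.0, 2.0),
    "noise_floor": (0.0, 1.0),
    "t_low": (0.0, 1.0),
    "score_tolerance": (0.0, 20.0),
}


@dataclass
class RunConfig:
    """All pipeline thresholds with documented defaults."""

    interactions: InteractionConfig = field(default_factory=InteractionConfig)
    pocket_radius: float = 4.0
    r2_threshold: float = 0.7
    delta_threshold: float = 0.1
    noise_floor: float = 0.1
    use_ec50_shift: bool = False
    t_low: float = 0.70
    score_tolerance: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name, (lo, hi) in _BOUNDS.items():
            value = getattr(self, name)
            if not lo <= value <= hi:
                raise DataError(
                    f"config {name}={value} outside [{lo}, {hi}]"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        inter = data.pop("interactions", {})
        cfg = cls(**data)
        cfg.interactions = InteractionConfig(**inter) if isinstance(
            inter, dict
        ) else inter
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def write(self, out_dir) -> None:
        from . import __version__

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        payload = self.to_dict()
        payload["bindmode_version"] = __version__
        with open(out_dir / "config.yaml", "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
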