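"""Run configuration and provenance plumbing for reproducible runs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .gating import GateConfig
from .models import DomainError

__all__ = ["RunConfig", "config_hash"]

_MODES = ("high_content", "timecourse", "simulate", "calibrate")

#: TIFF page order for high-content fields.  Channel-to-page mapping is
#: always explicit in config — microscope export dialects vary too much for
#: metadata guessing.
DEFAULT_CHANNEL_ORDER = ["blue", "green", "green", "green", "green", "red"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run; serialized into every output."""

    mode: str
    inputs: list = field(default_factory=list)
    output_dir: str = "out"
    seed: int = 0
    pixel_size: float = 0.65
    bit_depth: int = 14
    camera_offset: float = 100.0
    ball_radius_um: float = 146.0
    threshold: object = "auto"  # "auto" or counts
    channel_order: list = field(default_factory=lambda: list(DEFAULT_CHANNEL_ORDER))
    calibration: str = "rASAP"
    gate: GateConfig = field(default_factory=GateConfig)
    reference_vm: float = 0.0
    scene: dict | None = None  # SceneSpec overrides for simulate mode
    n_fields: int = 1

    def __post_init__(self):
        if self.mode not in _MODES:
            raise DomainError(f"mode must be one of {_MODES}")
        if self.mode == "simulate" and self.scene is None:
            self.scene = {}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("gate"), dict):
            d["gate"] = GateConfig(**d["gate"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonical JSON form of a config."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
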