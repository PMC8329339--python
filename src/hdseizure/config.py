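"""Pipeline configuration: one dataclass, lossless YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Every knob of the simulate → train → detect pipeline, with defaults.

    ``D`` and ``L`` set the hypervector dimension and order-pattern length;
    ``theta``/``tau``/``rho`` are the detection threshold, minimum duration
    (s) and refractory period (s); the three seeds keep the item memory,
    bundling tie-breaks and synthetic data on independent streams.
    """

    D: int = 10_000
    L: int = 9
    n_channels: int = 60
    fs: float = 512.0
    window_s: float = 1.0
    stride_s: float = 1.0
    theta: float = 0.0
    tau: float = 5.0
    rho: float = 30.0
    im_seed: int = 1
    tie_seed: int = 2
    synth_seed: int = 3
    bandpass: tuple | None = None  # (lo_hz, hi_hz), e.g. (0.5, 120.0); off by default

    def __post_init__(self):
        if self.D < 1 or self.L < 2 or self.n_channels < 1:
            raise ValueError("D >= 1, L >= 2 and n_channels >= 1 required")
        if min(self.fs, self.window_s, self.stride_s) <= 0:
            raise ValueError("fs, window_s and stride_s must be positive")
        if self.tau < 0 or self.rho < 0:
            raise ValueError("tau and rho must be non-negative")
        if self.bandpass is not None:
            self.bandpass = tuple(float(v) for v in self.bandpass)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        if d["bandpass"] is not None:
            d["bandpass"] = list(d["bandpass"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def override(self, **kwargs) -> "PipelineConfig":
        """New config with non-None keyword overrides applied (flags win)."""
        d = asdict(self)
        d.update({k: v for k, v in kwargs.items() if v is not None})
        return PipelineConfig.from_dict(d)
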