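"""Pipeline configuration: every stage's parameters in one serialisable object.

Defaults are the operating point of the method: 1.5-px quiet threshold
over 10-s windows, 0.3–3.0-Hz ideal temporal band-pass, amplification
α = 40, 8 pyramid orientations with adaptive depth, parabolic peak
refinement on.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

CONFIG_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class ScreeningConfig:
    threshold_px: float = 1.5
    window_s: float = 10.0
    stride_s: float = 1.0
    flow_stride_frames: int = 3
    flow_downsample: int = 2

    def validate(self) -> None:
        if self.threshold_px < 0 or self.window_s <= 0 or self.stride_s <= 0:
            raise ConfigError(f"invalid screening config {self}")


@dataclass(frozen=True)
class PbvmConfig:
    alpha: float = 40.0
    f_lo: float = 0.3
    f_hi: float = 3.0
    orientations: int = 8
    levels: int | None = None  # None = adaptive from frame size
    roi_mode: str = "fused"

    def validate(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ConfigError(f"need 0 < f_lo < f_hi, got [{self.f_lo}, {self.f_hi}]")
        if self.alpha < 0:
            raise ConfigError("alpha must be ≥ 0")
        if self.roi_mode not in ("fused", "separate"):
            raise ConfigError(f"roi_mode must be fused|separate, got {self.roi_mode!r}")


@dataclass(frozen=True)
class SpectralConfig:
    refine: bool = True
    require_peak_snr: bool = False
    snr_factor: float = 5.0

    def validate(self) -> None:
        if self.snr_factor <= 0:
            raise ConfigError("snr_factor must be positive")


@dataclass(frozen=True)
class IoConfig:
    fps_override: float | None = None
    color_mode: str = "gray"

    def validate(self) -> None:
        if self.color_mode not in ("gray", "pseudo_color"):
            raise ConfigError(f"unknown color_mode {self.color_mode!r}")


@dataclass(frozen=True)
class PipelineConfig:
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    pbvm: PbvmConfig = field(default_factory=PbvmConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    io: IoConfig = field(default_factory=IoConfig)
    seed: int = 0

    def validate(self, fps: float | None = None) -> "PipelineConfig":
        for sub in (self.screening, self.pbvm, self.spectral, self.io):
            sub.validate()
        if fps is not None and self.pbvm.f_hi >= fps / 2:
            raise ConfigError(f"f_hi={self.pbvm.f_hi} Hz at or above Nyquist for fps={fps}")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(klass, payload):
            fields = {f.name for f in dataclasses.fields(klass)}
            unknown = set(payload) - fields
            if unknown:
                raise ConfigError(f"unknown {klass.__name__} keys {sorted(unknown)}")
            return klass(**payload)

        return cls(
            screening=build(ScreeningConfig, data.get("screening", {})),
            pbvm=build(PbvmConfig, data.get("pbvm", {})),
            spectral=build(SpectralConfig, data.get("spectral", {})),
            io=build(IoConfig, data.get("io", {})),
            seed=int(data.get("seed", 0)),
        ).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    def digest(self) -> str:
        """Stable hash of the configuration, logged with every run."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
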