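"""Pipeline configuration: a strict YAML schema.

Unknown keys are rejected up front — a typo in a config must fail before any
compute starts, not silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
import yaml


class ConfigError(ValueError):
    pass


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}; allowed: {sorted(known)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            v = data[f.name]
            if hasattr(f.type, "__dataclass_fields__") or (
                    isinstance(f.default_factory, type) and hasattr(f.default_factory, "__dataclass_fields__")):
                sub_cls = f.default_factory if isinstance(f.default_factory, type) else f.type
                v = _build(sub_cls, v, f"{path}.{f.name}")
            kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class SimulateConfig:
    n_phantoms: int = 4
    shape: list = field(default_factory=lambda: [64, 72, 72])
    spacing: list = field(default_factory=lambda: [8.0, 4.8, 4.8])
    n_plaques: int | None = None       # None -> varied per phantom
    noise_sd: float = 600.0
    cd45_mode: str = "peripheral-rim"


@dataclass
class PreprocessConfig:
    target_size: list = field(default_factory=lambda: [64, 64])    # (width, height)
    clip_limit: float = 0.01
    tile_grid: list = field(default_factory=lambda: [8, 8])
    registration_size: list = field(default_factory=lambda: [96, 80, 80])
    network_size: list = field(default_factory=lambda: [32, 32, 32])
    binarization: str = "otsu"


@dataclass
class PlaqueNetConfig:
    depth: int = 2
    base_filters: int = 8
    lr: float = 1e-4
    max_epochs: int = 20
    patience: int = 25
    batch_size: int = 4
    threshold: float = 0.5
    annotation_stride: int = 5
    checkpoint: str | None = None      # reuse an existing model instead of training
    augment: bool = False


@dataclass
class AnatomyConfig:
    method: str = "atlas"              # atlas | unet
    n_atlases: int = 2
    iterations: list = field(default_factory=lambda: [60, 30, 15])
    checkpoint: str | None = None
    lr: float = 1e-5
    max_epochs: int = 20
    depth: int = 2
    base_filters: int = 4


@dataclass
class QuantifyConfig:
    connectivity: int = 26
    cd45_method: str = "otsu"


@dataclass
class StatsConfig:
    enabled: bool = True


@dataclass
class PipelineConfig:
    output_dir: str = "athero3d_out"
    seed: int = 0
    log_level: str = "INFO"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    plaque: PlaqueNetConfig = field(default_factory=PlaqueNetConfig)
    anatomy: AnatomyConfig = field(default_factory=AnatomyConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def validate(self) -> "PipelineConfig":
        if self.anatomy.method not in ("atlas", "unet"):
            raise ConfigError(f"anatomy.method must be 'atlas' or 'unet', got {self.anatomy.method!r}")
        if self.quantify.connectivity not in (6, 26):
            raise ConfigError(f"quantify.connectivity must be 6 or 26, got {self.quantify.connectivity}")
        return self


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _build(PipelineConfig, data, "config").validate()
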