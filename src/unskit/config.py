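"""Tool configuration: one YAML file binding all module parameters.

Unknown keys are rejected with their location, so typos never silently
fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .diagnostics import GelModel
from .gibson_simulator import GibsonParams
from .uns_designer import DesignConfig

__all__ = ["ToolConfig", "load_config", "default_config_yaml"]


@dataclass
class ToolConfig:
    design: DesignConfig = field(default_factory=DesignConfig)
    gibson: GibsonParams = field(default_factory=GibsonParams)
    gel: GelModel = field(default_factory=GelModel)
    registry: str | None = None
    uns: str | None = None
    output_dir: str = "."
    log_level: str = "INFO"


_SECTION_TYPES = {"design": DesignConfig, "gibson": GibsonParams, "gel": GelModel}
_SCALAR_KEYS = {"registry", "uns", "output_dir", "log_level"}


def _build_section(cls, data: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"{where}: unknown keys {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None = None) -> ToolConfig:
    if path is None:
        return ToolConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    unknown = set(data) - set(_SECTION_TYPES) - _SCALAR_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys {sorted(unknown)}")
    kwargs = {}
    for key, cls in _SECTION_TYPES.items():
        if key in data:
            if not isinstance(data[key], dict):
                raise ValueError(f"{path}: section {key!r} must be a mapping")
            kwargs[key] = _build_section(cls, data[key], f"{path}:{key}")
    for key in _SCALAR_KEYS:
        if key in data:
            kwargs[key] = data[key]
    return ToolConfig(**kwargs)


def default_config_yaml() -> str:
    cfg = ToolConfig()
    data = {
        "design": asdict(cfg.design),
        "gibson": asdict(cfg.gibson),
        "gel": asdict(cfg.gel),
        "registry": cfg.registry,
        "uns": cfg.uns,
        "output_dir": cfg.output_dir,
        "log_level": cfg.log_level,
    }
    return yaml.safe_dump(data, sort_keys=False)
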