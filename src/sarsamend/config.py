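"""Run configuration: defaults, YAML files and CLI overrides.

Precedence: CLI flags override file values, which override the built-in
defaults (the defaults of FusionConfig / FitConfig / SarsaConfig).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .amendment import SarsaConfig
from .detection import FusionConfig
from .fitting import FitConfig

__all__ = ["RunConfig", "load_run_config"]


@dataclass(frozen=True)
class RunConfig:
    detection: FusionConfig = field(default_factory=FusionConfig)
    fitting: FitConfig = field(default_factory=FitConfig)
    amendment: SarsaConfig = field(default_factory=SarsaConfig)
    seed: int = 0


def _build(cls, file_section: dict, overrides: dict):
    known = {f.name for f in fields(cls)}
    bad = set(file_section) - known
    if bad:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(bad)}")
    merged = dict(file_section)
    merged.update({k: v for k, v in overrides.items() if v is not None and k in known})
    for key in ("weights", "sigmas"):
        if isinstance(merged.get(key), list):
            merged[key] = tuple(merged[key])
    return cls(**merged)


def load_run_config(path=None, *, detection=None, fitting=None, amendment=None,
                    seed=None) -> RunConfig:
    """Assemble a RunConfig from an optional YAML file plus CLI overrides.

    The YAML file may contain sections ``detection``, ``fitting``,
    ``amendment`` and a top-level ``seed``, each mirroring the
    corresponding config dataclass.
    """
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
    cfg_seed = seed if seed is not None else int(data.get("seed", 0))
    return RunConfig(
        detection=_build(FusionConfig, data.get("detection", {}) or {}, detection or {}),
        fitting=_build(FitConfig, data.get("fitting", {}) or {}, fitting or {}),
        amendment=_build(SarsaConfig, data.get("amendment", {}) or {}, amendment or {}),
        seed=cfg_seed,
    )
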