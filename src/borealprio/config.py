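"""YAML run configuration for the command-line interface.

Only the fields a user typically varies are exposed; everything else
falls back to the library defaults.  Two top-level sections are
recognised: ``landscape`` (grid geometry and baseline distributions)
and ``ensemble`` (iteration count, variants, toggles).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Dict, Tuple

import yaml

from .ensemble import EnsembleConfig
from .landscape import LandscapeConfig

__all__ = ["load_run_config", "dump_run_config"]


def _coerce(cls, section: Dict[str, Any]):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in section.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_run_config(path: str | Path) -> Tuple[LandscapeConfig, EnsembleConfig]:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    landscape = _coerce(LandscapeConfig, doc.get("landscape", {}))
    ensemble = _coerce(EnsembleConfig, doc.get("ensemble", {}))
    return landscape, ensemble


def dump_run_config(path: str | Path, landscape: LandscapeConfig,
                    ensemble: EnsembleConfig) -> None:
    def clean(obj) -> Dict[str, Any]:
        out = {}
        for key, value in dataclasses.asdict(obj).items():
            if isinstance(value, tuple):
                value = list(value)
            out[key] = value
        return out

    with open(path, "w") as fh:
        yaml.safe_dump({"landscape": clean(landscape),
                        "ensemble": clean(ensemble)}, fh, sort_keys=False)
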