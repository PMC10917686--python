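"""Declarative run configuration.

A run is described by a YAML file::

    preset: desk            # or paper_scale
    seed: 7
    params:                 # overrides, grouped by parameter block
      plasticity:
        A: 0.008
      protocol:
        T_consolidation: 1200.0
    manipulations:
      - kind: block_inhibitory_plasticity
        phases: [consolidation]
      - kind: block_neurons
        phases: [recall]
        target: inh

Unknown keys anywhere in the file are rejected with the offending key
named, so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import List, Optional

import yaml

from .params import ModelParams, PRESETS
from .protocol import Manipulation

__all__ = ["RunConfig", "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for malformed configuration files."""


@dataclass
class RunConfig:
    """Fully resolved configuration of one run."""

    params: ModelParams
    seed: int = 0
    manipulations: List[Manipulation] = field(default_factory=list)
    out_dir: Optional[str] = None
    log_level: str = "info"

    def resolved_dict(self) -> dict:
        params = self.params.to_dict()
        params.pop("preset", None)
        return {
            "preset": self.params.preset,
            "seed": self.seed,
            "params": params,
            "manipulations": [
                {"kind": m.kind, "phases": list(m.phases),
                 "target": (list(map(int, m.target))
                            if m.target is not None
                            and not isinstance(m.target, str)
                            else m.target)}
                for m in self.manipulations],
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }


_TOP_KEYS = {"preset", "seed", "params", "manipulations", "out_dir",
             "log_level"}


def _apply_overrides(mp: ModelParams, over: dict) -> None:
    blocks = {f.name: getattr(mp, f.name) for f in dc_fields(mp)
              if f.name != "preset"}
    for bname, bvals in over.items():
        if bname not in blocks:
            raise ConfigError(f"unknown parameter block {bname!r}")
        if not isinstance(bvals, dict):
            raise ConfigError(f"params.{bname} must be a mapping")
        block = blocks[bname]
        valid = {f.name for f in dc_fields(block)}
        for key, val in bvals.items():
            if key not in valid:
                raise ConfigError(
                    f"unknown parameter params.{bname}.{key}")
            setattr(block, key, val)


def load_config(path) -> RunConfig:
    """Load and fully resolve a YAML run configuration.

    An empty file resolves to all defaults of the requested preset
    (``desk`` if none given).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key {sorted(unknown)[0]!r}")
    preset = raw.get("preset", "desk")
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; choose from "
                          f"{sorted(PRESETS)}")
    mp = PRESETS[preset]()
    _apply_overrides(mp, raw.get("params") or {})
    mp.validate()
    manips = []
    for i, m in enumerate(raw.get("manipulations") or []):
        if not isinstance(m, dict):
            raise ConfigError(f"manipulations[{i}] must be a mapping")
        bad = set(m) - {"kind", "phases", "target"}
        if bad:
            raise ConfigError(
                f"unknown manipulation key {sorted(bad)[0]!r}")
        try:
            manips.append(Manipulation(
                kind=m.get("kind", ""),
                phases=tuple(m.get("phases", ("consolidation",))),
                target=m.get("target")))
        except ValueError as e:
            raise ConfigError(f"manipulations[{i}]: {e}") from e
    return RunConfig(params=mp, seed=int(raw.get("seed", 0)),
                     manipulations=manips,
                     out_dir=raw.get("out_dir"),
                     log_level=str(raw.get("log_level", "info")))


def save_config(cfg: RunConfig, path) -> None:
    """Write the fully resolved configuration (round-trips through
    :func:`load_config` to an identical resolved config)."""
    Path(path).write_text(yaml.safe_dump(cfg.resolved_dict(),
                                         sort_keys=False))
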