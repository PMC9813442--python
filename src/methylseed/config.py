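"""Flat key=value run configuration with strict key checking.

The config file is plain text, one ``section.key = value`` per line, ``#``
comments allowed. Section prefixes map onto the parameter dataclasses
(``genome.*`` -> GenomeSpec, ``model.*`` -> MethModel, ``dmr.*`` -> DmrParams,
``imprint.*`` -> ImprintSpec) plus a handful of pipeline-level keys. Unknown
keys are rejected so typos cannot silently fall back to defaults; the
effective configuration is echoed into every run manifest.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

from .dmr import DmrParams
from .simulate import GenomeSpec, ImprintSpec, MethModel

__all__ = ["RunConfig", "load_config", "KNOWN_KEYS"]

_SECTIONS = {
    "genome": GenomeSpec,
    "model": MethModel,
    "dmr": DmrParams,
    "imprint": ImprintSpec,
}

_EXTRA_KEYS: dict[str, Any] = {
    "sim.mean_depth": 20.0,
    "sim.nonconversion": 0.01,
    "profile.flank": 3000,
    "profile.bin_size": 100,
    "profile.min_informative": 10,
    "profile.min_frac": 0.5,
    "qc.tissue": "endosperm",
    "qc.tolerance": 0.10,
    "compare.test": "paired",
    "compare.min_total": 10,
}


def _dataclass_defaults(prefix: str, cls) -> dict[str, Any]:
    out = {}
    for f in dataclasses.fields(cls):
        if isinstance(f.default, (int, float, str, bool)):
            out[f"{prefix}.{f.name}"] = f.default
    return out


def _known_keys() -> dict[str, Any]:
    keys: dict[str, Any] = {}
    for prefix, cls in _SECTIONS.items():
        keys.update(_dataclass_defaults(prefix, cls))
    keys.update(_EXTRA_KEYS)
    return keys


KNOWN_KEYS = _known_keys()


def _coerce(key: str, raw: str, default: Any) -> Any:
    if isinstance(default, bool):
        if raw.lower() in ("true", "1", "yes"):
            return True
        if raw.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"config key {key}: cannot parse boolean from {raw!r}")
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    return raw


class RunConfig:
    """Effective configuration: defaults overlaid with file overrides."""

    def __init__(self, overrides: dict[str, Any] | None = None):
        self.values: dict[str, Any] = dict(KNOWN_KEYS)
        for key, raw in (overrides or {}).items():
            if key not in self.values:
                raise KeyError(f"unknown config key: {key}")
            if isinstance(raw, str):
                self.values[key] = _coerce(key, raw, KNOWN_KEYS[key])
            else:
                self.values[key] = raw

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def section(self, prefix: str) -> dict[str, Any]:
        plen = len(prefix) + 1
        return {k[plen:]: v for k, v in self.values.items() if k.startswith(prefix + ".")}

    def genome_spec(self) -> GenomeSpec:
        return GenomeSpec(**self.section("genome"))

    def meth_model(self) -> MethModel:
        return MethModel(**self.section("model"))

    def dmr_params(self) -> DmrParams:
        return DmrParams(**self.section("dmr"))

    def imprint_spec(self) -> ImprintSpec:
        return ImprintSpec(**self.section("imprint"))

    def as_dict(self) -> dict[str, Any]:
        return dict(sorted(self.values.items()))


def load_config(path: str | Path | None) -> RunConfig:
    """Parse a flat key=value config file; None gives all defaults."""
    if path is None:
        return RunConfig()
    overrides: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key = value")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key in overrides:
                raise ValueError(f"{path}: line {lineno}: duplicate key {key}")
            overrides[key] = raw
    return RunConfig(overrides)
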