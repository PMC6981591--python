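"""Run configuration from YAML or JSON files.

A config file holds generator parameters, the desirability band, alpha
and the seed, e.g.::

    seed: 7
    alpha: 0.05
    desirability: {low: 22, high: 40}
    cutoff_target: 28.67
    generator:
      n: 46
      mode: genotype
      residual_sd: 2.0

Unknown keys are rejected rather than ignored, so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .desirability import DesirabilitySpec
from .pipeline import RunConfig
from .simulate import GeneratorParams


def _build(cls, data: dict, where: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"{where}: unknown key(s) {sorted(unknown)}; "
                         f"allowed: {sorted(fields)}")
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML (or JSON — a YAML subset) file into a :class:`RunConfig`."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    data = dict(data)
    if "generator" in data:
        data["generator"] = _build(GeneratorParams, data["generator"],
                                   f"{path}: generator")
    if "desirability" in data:
        data["desirability"] = _build(DesirabilitySpec, data["desirability"],
                                      f"{path}: desirability")
    return _build(RunConfig, data, str(path))


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write a config back out as JSON (valid YAML) for run provenance."""
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if hasattr(obj, "tolist"):
            return obj.tolist()
        if isinstance(obj, Path):
            return str(obj)
        return obj

    Path(path).write_text(json.dumps(encode(config), indent=2, default=str))
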