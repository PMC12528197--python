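"""Run configuration: YAML-backed, fully reproducible.

A :class:`RunConfig` bundles the generator, filter, model and training
parameter blocks.  A persisted config plus its seed fully determines a
run; every field can be overridden from the command line with
``--set section.field=value``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .model import ModelConfig
from .preprocessing import FilterSpec
from .synth import SynthSpec
from .training import TrainSpec

__all__ = ["RunConfig", "load_config", "parse_override"]


@dataclass
class RunConfig:
    synth: SynthSpec = field(default_factory=SynthSpec)
    filter: FilterSpec = field(default_factory=FilterSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainSpec = field(default_factory=TrainSpec)
    window_s: float = 2.0
    overlap_s: float = 0.0
    run_ica: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"] = self.model.to_dict()
        return d

    def save(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)


_SECTIONS = {"synth": SynthSpec, "filter": FilterSpec, "model": ModelConfig,
             "train": TrainSpec}


def load_config(path=None, overrides: tuple[str, ...] = ()) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides."""
    raw: dict = {}
    if path is not None:
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
    for ov in overrides:
        key, value = parse_override(ov)
        node = raw
        *parents, leaf = key.split(".")
        for part in parents:
            node = node.setdefault(part, {})
        node[leaf] = value

    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.pop(name, {})
        if not isinstance(section, dict):
            raise ValueError(f"config section {name!r} must be a mapping")
        if name == "train" and "split" in section:
            section["split"] = tuple(section["split"])
        try:
            kwargs[name] = cls(**section)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid config in section {name!r}: {exc}") from exc
    for key in ("window_s", "overlap_s", "run_ica", "seed"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if raw:
        raise ValueError(f"unknown config keys: {sorted(raw)}")
    return RunConfig(**kwargs)


def parse_override(text: str) -> tuple[str, object]:
    """Parse ``section.field=value`` with YAML-typed values."""
    if "=" not in text:
        raise ValueError(f"override {text!r} must look like section.field=value")
    key, value = text.split("=", 1)
    return key.strip(), yaml.safe_load(value)
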