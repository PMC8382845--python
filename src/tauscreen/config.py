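"""YAML configuration: one file holds every tunable parameter with defaults.

CLI flags override file values; each run logs the fully resolved parameter
set, so the (at most three) run-to-run intensity adjustments are always
explicit and auditable.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Any

import yaml

from .screen import QCThresholds
from .segment import SegmentationParams
from .simulate import (
    EffectParams,
    NeuriteTreeConfig,
    NoiseModel,
    SynthFieldConfig,
)

log = logging.getLogger("tauscreen")


def _asdict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _asdict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _asdict(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _build(cls, data: dict | None):
    """Instantiate a parameter dataclass from a (possibly partial) mapping."""
    data = dict(data or {})
    kwargs = {}
    nested = {"neurite_tree": NeuriteTreeConfig, "noise": NoiseModel,
              "effect": EffectParams}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data.pop(f.name)
        if f.name in nested and isinstance(v, dict):
            v = _build(nested[f.name], v)
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    if data:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(data)}")
    return cls(**kwargs)


@dataclasses.dataclass
class RunConfig:
    """Resolved parameter set for one pipeline run."""

    simulate: SynthFieldConfig
    segmentation: SegmentationParams
    qc: QCThresholds

    def to_dict(self) -> dict:
        return {"simulate": _asdict(self.simulate),
                "segmentation": _asdict(self.segmentation),
                "qc": _asdict(self.qc)}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML config (defaults when absent), apply overrides, log it."""
    doc: dict = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
    for section, values in (overrides or {}).items():
        doc.setdefault(section, {}).update(values)
    cfg = RunConfig(
        simulate=_build(SynthFieldConfig, doc.get("simulate")),
        segmentation=_build(SegmentationParams, doc.get("segmentation")),
        qc=_build(QCThresholds, doc.get("qc")),
    )
    log.info("resolved parameters:\n%s",
             yaml.safe_dump(cfg.to_dict(), sort_keys=False))
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
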