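"""Structured simulation configuration: defaults, validation, (de)serialization.

A configuration file is YAML (JSON, being a YAML subset, also loads) with
optional sections ``device``, ``array``, ``threshold``, ``analog``,
``timing``, ``variation`` and a top-level ``seed``.  Every omitted field
takes the documented default — an empty file yields the implemented-chip
configuration (16 axons × 16 dendrites, threshold 5 alpha units,
reference code value 2).  Unknown keys and violated invariants raise
``ConfigError`` naming the offending key and constraint.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .cluster import Cluster, StimulusSchedule, TimingConfig
from .device import DeviceParams
from .neuron import AnalogConfig
from .synapse import (
    DEFAULT_REF_VALUE,
    SynapseMatrix,
    ThresholdBlock,
    program_weights,
)
from .variation import VariationConfig


class ConfigError(ValueError):
    """A configuration file problem, with the key and constraint named."""


@dataclass(frozen=True)
class ArraySpec:
    """User-facing description of the synapse array in alpha units."""

    K: int = 16
    N: int = 16
    weights: list | None = None  # K×N signed alpha units; default all-zero
    ref_value: int = DEFAULT_REF_VALUE
    shape: str = "thermometer"
    n_cells: int | None = None

    def build(self) -> SynapseMatrix:
        if self.weights is None:
            W = np.zeros((self.K, self.N), dtype=int)
        else:
            W = np.asarray(self.weights, dtype=int)
            if W.ndim != 2:
                raise ConfigError(
                    f"array.weights must be a 2-D table, got shape {W.shape}"
                )
        return program_weights(W, self.ref_value, self.shape, self.n_cells)


@dataclass(frozen=True)
class ThresholdSpec:
    """User-facing description of the shared threshold block."""

    theta_units: int = 5
    ref_value: int = DEFAULT_REF_VALUE
    shape: str = "thermometer"
    n_cells: int | None = None

    def build(self) -> ThresholdBlock:
        return ThresholdBlock.from_units(
            self.theta_units, self.ref_value, self.shape, self.n_cells
        )


@dataclass
class SimulationConfig:
    """Fully validated simulation configuration with concrete sub-objects."""

    device: DeviceParams = field(default_factory=DeviceParams)
    array: ArraySpec = field(default_factory=ArraySpec)
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    analog: AnalogConfig = field(default_factory=AnalogConfig)
    timing: TimingConfig = field(default_factory=TimingConfig)
    variation: VariationConfig = field(default_factory=VariationConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        self.matrix = self.array.build()
        self.threshold_block = self.threshold.build()

    def build_cluster(self, offsets=None) -> Cluster:
        return Cluster(
            self.matrix,
            self.threshold_block,
            analog=self.analog,
            timing=self.timing,
            params=self.device,
            offsets=offsets,
        )


_SECTIONS = {
    "device": DeviceParams,
    "array": ArraySpec,
    "threshold": ThresholdSpec,
    "analog": AnalogConfig,
    "timing": TimingConfig,
    "variation": VariationConfig,
}


def _build_section(name: str, cls: type, data: dict[str, Any]) -> Any:
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {name!r}; "
            f"valid keys: {sorted(valid)}"
        )
    if name == "variation":
        for k in ("offset_pre", "offset_post"):
            if k in data:
                data[k] = {
                    kind: tuple(pair) for kind, pair in dict(data[k]).items()
                }
        if "alpha_range" in data:
            data["alpha_range"] = tuple(data["alpha_range"])
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"section {name!r}: {exc}") from exc


def load_config(path: str | Path) -> SimulationConfig:
    """Load, default-fill, and validate a YAML/JSON configuration file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping, got {type(raw)}")
    return config_from_dict(raw, source=str(path))


def config_from_dict(raw: dict[str, Any], source: str = "<dict>") -> SimulationConfig:
    unknown = set(raw) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ConfigError(
            f"{source}: unknown section(s) {sorted(unknown)}; valid sections: "
            f"{sorted(_SECTIONS)} plus 'seed'"
        )
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"{source}: section {name!r} must be a mapping")
        kwargs[name] = _build_section(name, cls, dict(section))
    kwargs["seed"] = int(raw.get("seed", 0))
    return SimulationConfig(**kwargs)


def config_to_dict(cfg: SimulationConfig) -> dict[str, Any]:
    """Serializable dict form; inverse of :func:`config_from_dict`."""
    out: dict[str, Any] = {}
    for name in _SECTIONS:
        obj = getattr(cfg, name)
        d = dataclasses.asdict(obj)
        if name == "array":
            W = cfg.matrix.alpha_matrix()
            d["weights"] = W.tolist()
            d["K"], d["N"] = W.shape
        if name == "variation":
            d["alpha_range"] = list(d["alpha_range"])
            for k in ("offset_pre", "offset_post"):
                d[k] = {kind: list(pair) for kind, pair in d[k].items()}
        if name == "timing" and d.get("adjacency") is not None:
            d["adjacency"] = {int(k): list(v) for k, v in d["adjacency"].items()}
        out[name] = d
    out["seed"] = cfg.seed
    return out


def save_config(cfg: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def simulate(
    cfg: SimulationConfig,
    schedule: StimulusSchedule,
    n_ticks: int | None = None,
    record_traces: bool = False,
):
    """Build the cluster from ``cfg`` and run the schedule (ideal chip)."""
    return cfg.build_cluster().run(schedule, n_ticks, record_traces=record_traces)
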