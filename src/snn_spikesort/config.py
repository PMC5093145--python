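"""Run configuration: nested sections, YAML/JSON loading, strict validation.

A run configuration bundles every tunable of the pipeline.  Loading is
strict: unknown keys are rejected by name, and every value passes through
the owning dataclass's invariants.  Omitted fields fall back to the
package defaults (the reference LIF table, 32/5 topology, 10 devices per
synapse, the 30 uA pulse conditions, the 20 ms / 10 s evaluation
constants).
"""

from __future__ import annotations

import dataclasses
import hashlib
import typing
from dataclasses import dataclass, field

import yaml

from .encoder import FilterBankConfig
from .errors import ConfigurationError
from .evaluation import EvaluationConfig
from .lif import LIFParams, LAYER1_DEFAULTS, LAYER2_DEFAULTS
from .network import NetworkConfig, STDPParams
from .optimizer import GAConfig
from .oxram import SynapseConfig
from . import synth as _synth

__all__ = ["SynthSection", "RunConfig", "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class SynthSection:
    """Declarative form of the synthetic-data generator settings."""

    preset: str = "staged_two_unit"
    scale: float = 0.1
    rate_hz: float = 20000.0
    unit_rate_hz: float = 3.0
    noise_sigma: float = 0.05
    lf_noise_amp: float = 0.1
    lf_noise_hz: float = 20.0
    noise_color: str = "white"
    refractory_s: float = 0.05
    seed: int = 0

    def to_synth_config(self, seed: int | None = None) -> _synth.SynthConfig:
        if self.preset != "staged_two_unit":
            raise ConfigurationError(f"unknown synth preset {self.preset!r}")
        return _synth.staged_two_unit(
            scale=self.scale,
            seed=self.seed if seed is None else seed,
            rate_hz=self.rate_hz,
            unit_rate_hz=self.unit_rate_hz,
            noise_sigma=self.noise_sigma,
            lf_noise_amp=self.lf_noise_amp,
            lf_noise_hz=self.lf_noise_hz,
            noise_color=self.noise_color,
            refractory_s=self.refractory_s,
        )


@dataclass(frozen=True)
class RunConfig:
    """All sections of one reproducible run."""

    seed: int = 0
    filterbank: FilterBankConfig = field(default_factory=FilterBankConfig)
    layer1: LIFParams = LAYER1_DEFAULTS
    layer2: LIFParams = LAYER2_DEFAULTS
    synapse: SynapseConfig = field(default_factory=SynapseConfig)
    stdp: STDPParams = field(default_factory=STDPParams)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    synth: SynthSection = field(default_factory=SynthSection)
    ga: GAConfig = field(default_factory=GAConfig)


def _build(cls, data, path: str):
    """Construct a dataclass from a mapping, rejecting unknown keys."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"section '{path}' must be a mapping")
    hints = typing.get_type_hints(cls)
    known = {f.name: hints.get(f.name) for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ConfigurationError(f"unknown configuration key '{path}.{key}'")
        tp = known[key]
        if dataclasses.is_dataclass(tp) and isinstance(value, (dict, type(None))):
            kwargs[key] = _build(tp, value, f"{path}.{key}")
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"section '{path}': {exc}") from exc


def load_config(path_or_mapping) -> RunConfig:
    """Load and validate a run configuration from YAML/JSON (or a dict).

    Sections and fields omitted from the file take the package defaults;
    section seeds (network, synth, ga) inherit the master ``seed`` unless
    set explicitly.
    """
    if isinstance(path_or_mapping, dict):
        data = dict(path_or_mapping)
    else:
        with open(path_or_mapping) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("top-level configuration must be a mapping")
    explicit_seeds = {
        section: isinstance(data.get(section), dict) and "seed" in data[section]
        for section in ("network", "synth", "ga")
    }
    cfg = _build(RunConfig, data, "config")
    for section, has_own in explicit_seeds.items():
        if not has_own:
            cfg = dataclasses.replace(
                cfg, **{section: dataclasses.replace(getattr(cfg, section), seed=cfg.seed)}
            )
    return cfg


def save_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Stable SHA-256 of the fully resolved configuration."""
    canonical = yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
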