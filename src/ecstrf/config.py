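"""Versioned YAML experiment configuration.

An :class:`ExperimentConfig` fully determines a scenario run: the ensemble
generator parameters, the noise variances, the information–cost tradeoff,
the SNR / correlation ladders, the analysis thresholds and the seed.  Every
output artifact records the config hash, so any artifact is regenerable
from its embedded config + seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .ensembles import DEFAULT_DECAY_RATE

__all__ = ["ExperimentConfig", "ConfigError", "validate_config", "load_config"]

SCHEMA_VERSION = 1

SCENARIOS = ("srf-fig3", "srf-snr-ladder", "srf-corr", "trf", "strf-2d")


class ConfigError(ValueError):
    """Invalid experiment configuration; the message names the field."""


@dataclass
class ExperimentConfig:
    scenario: str = "srf-fig3"
    # ensemble
    n_channels: int = 250
    n_samples: int = 250
    intensity_scale: float = 10.0
    decay_rate: float = DEFAULT_DECAY_RATE
    smoothing_length: float = 5.0
    freq_step: float = 0.02              # octaves per channel
    time_step: float = 1e-3              # seconds per temporal tap
    n_temporal: int = 64                 # taps for trf / strf grids
    n_spectral: int = 32                 # spectral-modulation rows for strf-2d
    corr_params: tuple = (1.0, 0.03)     # (lambda_f octaves, lambda_t seconds)
    # noise and tradeoff
    input_noise_var: float = 1.0
    encoding_noise_var: float = 1.0
    tradeoff: float = 4.0
    # ladders
    scale_ladder: tuple = (0.03, 0.1, 0.3, 1.0, 3.0, 10.0)
    smoothing_ladder: tuple = (2.0, 10.0)
    # analysis thresholds
    mtf_rel_threshold: float = 0.05
    bandpass_margin: float = 0.10
    lobe_noise_floor: float = 0.05
    # reproducibility
    seed: int = 0
    outdir: str = "ecstrf-out"
    schema_version: int = SCHEMA_VERSION
    extra: dict = field(default_factory=dict)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_POSITIVE = (
    "intensity_scale",
    "smoothing_length",
    "freq_step",
    "time_step",
    "input_noise_var",
    "encoding_noise_var",
    "tradeoff",
)


def validate_config(data: dict) -> ExperimentConfig:
    """Normalise a raw mapping into an ExperimentConfig, or raise ConfigError."""
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    known = {f for f in ExperimentConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    version = data.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"schema_version: expected {SCHEMA_VERSION}, got {version}")
    for key in ("scale_ladder", "smoothing_ladder", "corr_params"):
        if key in data:
            data = {**data, key: tuple(data[key])}
    cfg = ExperimentConfig(**data)
    if cfg.scenario not in SCENARIOS:
        raise ConfigError(f"scenario: must be one of {SCENARIOS}, got {cfg.scenario!r}")
    for name in _POSITIVE:
        if getattr(cfg, name) <= 0:
            raise ConfigError(f"{name}: must be strictly positive")
    if cfg.decay_rate < 0:
        raise ConfigError("decay_rate: must be nonnegative")
    if cfg.n_channels < 2:
        raise ConfigError("n_channels: must be >= 2")
    if cfg.n_samples < 2:
        raise ConfigError("n_samples: must be >= 2")
    if not 0 < cfg.mtf_rel_threshold < 1:
        raise ConfigError("mtf_rel_threshold: must be in (0, 1)")
    if any(s <= 0 for s in cfg.scale_ladder):
        raise ConfigError("scale_ladder: entries must be positive")
    if any(s <= 0 for s in cfg.smoothing_ladder):
        raise ConfigError("smoothing_ladder: entries must be positive")
    return cfg


def load_config(path) -> ExperimentConfig:
    """Read and validate a YAML config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return validate_config(data)
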