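"""YAML run configuration: schema-checked, unknown keys rejected, defaults
injected and echoed back so every run is reproducible from its provenance
record alone."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    """A configuration file violated the schema; the message names the key."""


@dataclass
class RunConfig:
    seed: int = 42
    outdir: str = "trfscreen_out"
    # simulation
    n_trnas: int = 50
    utr_len: int = 300
    frag_len: int = 22
    mismatches: int = 0
    gu_wobbles: int = 0
    n_genes: int = 2000
    n_samples_per_group: int = 6
    # screen thresholds
    mfe_max: float = -20.0
    comp_min: float = 72.0
    window: int = 40
    step: int = 10
    # DEG thresholds
    log2fc_thresh: float = 1.0
    alpha: float = 0.05
    # misc
    verbosity: str = "info"


_BOOL_OK = {"verbosity"}  # string-typed keys


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; returns a RunConfig with defaults filled.

    Unknown keys are rejected; a wrongly typed value raises
    :class:`ConfigError` naming the key.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = {f.name: f.type for f in fields(RunConfig)}
    defaults = RunConfig()
    for key, value in raw.items():
        if key not in known:
            raise ConfigError(f"unknown config key {key!r}")
        default_val = getattr(defaults, key)
        if isinstance(default_val, bool):
            ok = isinstance(value, bool)
        elif isinstance(default_val, int):
            ok = isinstance(value, int) and not isinstance(value, bool)
        elif isinstance(default_val, float):
            ok = isinstance(value, (int, float)) and not isinstance(value, bool)
        else:
            ok = isinstance(value, str)
        if not ok:
            raise ConfigError(
                f"config key {key!r}: expected {type(default_val).__name__}, "
                f"got {type(value).__name__}"
            )
    merged = asdict(defaults)
    merged.update(raw)
    cfg = RunConfig(**merged)
    if cfg.alpha <= 0 or cfg.alpha >= 1:
        raise ConfigError("config key 'alpha': must be in (0, 1)")
    return cfg
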