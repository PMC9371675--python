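"""Run configuration: a YAML file with three blocks (params / theory / run).

Example::

    params:
      m: 1
      K: 1000          # placeholder; overridden per grid point
      beta: 0.01
      sigma: 0.01
    theory:
      gamma_n: 0.2
    run:
      N_grid: [500, 1000, 2000, 4000, 8000]
      n_reps: 200
      base_seed: 1
      output_dir: out

Unknown keys anywhere are rejected, so a typo cannot silently fall back to a
default. Configurations round-trip losslessly through :func:`to_dict`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import DriveParams, TheoryConstants

__all__ = ["RunSettings", "RunConfig", "load_config", "config_hash"]


class ConfigError(ValueError):
    """Invalid or malformed run configuration."""


@dataclass
class RunSettings:
    """Batch-execution block: grid, replicate count, seeding and output."""

    N_grid: list = field(default_factory=lambda: [1000])
    n_reps: int = 500
    base_seed: int = 0
    output_dir: str = "multidrive_out"
    emit_trajectories: bool = False

    def __post_init__(self):
        if not self.N_grid or any(int(n) < 1 for n in self.N_grid):
            raise ConfigError("run.N_grid must be a non-empty list of sizes >= 1")
        self.N_grid = [int(n) for n in self.N_grid]
        if self.n_reps < 1:
            raise ConfigError("run.n_reps must be >= 1")


@dataclass
class RunConfig:
    params: DriveParams
    theory: TheoryConstants
    run: RunSettings

    def to_dict(self) -> dict:
        d = {
            "params": dataclasses.asdict(self.params),
            "theory": dataclasses.asdict(self.theory),
            "run": dataclasses.asdict(self.run),
        }
        return d


def _build(cls, block: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}' block: {sorted(unknown)}")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{name}' block: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    unknown = set(raw) - {"params", "theory", "run"}
    if unknown:
        raise ConfigError(f"unknown top-level block(s): {sorted(unknown)}")
    params_block = raw.get("params")
    if params_block is None:
        raise ConfigError("missing required 'params' block (must set at least m and K)")
    theory_block = dict(raw.get("theory") or {})
    if "gamma_m" in theory_block:
        theory_block["gamma_m"] = {int(k): float(v) for k, v in theory_block["gamma_m"].items()}
    params = _build(DriveParams, dict(params_block), "params")
    theory = _build(TheoryConstants, theory_block, "theory")
    run = _build(RunSettings, dict(raw.get("run") or {}), "run")
    return RunConfig(params=params, theory=theory, run=run)


def config_hash(config: RunConfig) -> str:
    """Stable hash of the full configuration, for run manifests."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
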