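"""Structured run configuration, stage-scoped seeding and the run manifest.

A run is described by one YAML file with sections for the synthetic panel,
clustering, model training, baselines and attribution.  Every random
operation draws from a seed derived deterministically from the master seed
and the stage name, so adding or re-running one stage never shifts another
stage's randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .models import BaselineConfig
from .nn import TrainingConfig
from .synth import SyntheticConfig


class ConfigError(ValueError):
    """The run configuration is invalid; the message lists every problem."""


@dataclass
class ClusterSettings:
    k: int = 6
    candidate_ks: tuple[int, ...] = (2, 4, 6, 8)
    select_k: bool = False
    n_restarts: int = 25


@dataclass
class RunConfig:
    out_dir: str = "runs/default"
    stress_year: int = 2012
    master_seed: int = 0
    log_level: str = "INFO"
    panel_dir: str | None = None     # read an existing panel instead of simulating
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    clustering: ClusterSettings = field(default_factory=ClusterSettings)
    training: TrainingConfig = field(default_factory=TrainingConfig.reduced)
    attribution_training: TrainingConfig = field(default_factory=TrainingConfig.attribution)
    baselines: BaselineConfig = field(default_factory=BaselineConfig)
    unknown_keys: list = field(default_factory=list)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2^31."""
        return stage_seed(self.master_seed, stage)

    def config_hash(self) -> str:
        payload = json.dumps(_serialize(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    return zlib.crc32(f"{master_seed}:{stage}".encode()) % (2 ** 31)


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if hasattr(obj, "item") and callable(obj.item):  # numpy scalar
        return obj.item()
    return obj


def _serialize(cfg: RunConfig) -> dict:
    """Configuration as plain data, without runtime-only fields."""
    payload = _as_jsonable(cfg)
    payload.pop("unknown_keys", None)
    return payload


_SECTIONS = {
    "synthetic": SyntheticConfig,
    "clustering": ClusterSettings,
    "training": TrainingConfig,
    "attribution_training": TrainingConfig,
    "baselines": BaselineConfig,
}
_TOP_KEYS = {"out_dir", "stress_year", "master_seed", "log_level", "panel_dir"}


def _build_section(cls, payload: dict, errors: list, warnings: list, prefix: str):
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in payload.items():
        if key not in names:
            warnings.append(f"unknown key {prefix}{key} (preserved in manifest)")
            continue
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{prefix.rstrip('.') or 'top level'}: {exc}")
        return cls()


def validate_config(path: str | Path) -> RunConfig:
    """Load, validate and normalize a YAML run configuration.

    Unknown keys produce warnings preserved on the returned object; invalid
    values raise :class:`ConfigError` listing every problem at once.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    errors: list[str] = []
    warnings: list[str] = []
    kwargs = {}
    for key in _TOP_KEYS & raw.keys():
        kwargs[key] = raw[key]
    for name, cls in _SECTIONS.items():
        if name in raw:
            if not isinstance(raw[name], dict):
                errors.append(f"section {name!r} must be a mapping")
                continue
            kwargs[name] = _build_section(cls, raw[name], errors, warnings, f"{name}.")
    for key in raw:
        if key not in _TOP_KEYS and key not in _SECTIONS:
            warnings.append(f"unknown key {key} (preserved in manifest)")
    if "training" not in kwargs:
        kwargs["training"] = TrainingConfig.reduced()
    if "attribution_training" not in kwargs:
        kwargs["attribution_training"] = TrainingConfig.attribution()
    if errors:
        raise ConfigError("; ".join(errors))
    cfg = RunConfig(**kwargs)
    cfg.unknown_keys = warnings
    return cfg


def default_config_yaml() -> str:
    """The full default configuration as a YAML document."""
    return yaml.safe_dump(_serialize(RunConfig()), sort_keys=False)


def write_manifest(run_dir: str | Path, config: RunConfig, stages_run: list[str]) -> Path:
    """List every artifact in the run directory with a checksum."""
    run_dir = Path(run_dir)
    files = {}
    for p in sorted(run_dir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            files[str(p.relative_to(run_dir))] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    manifest = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "stages_run": stages_run,
        "stage_seeds": {s: config.stage_seed(s) for s in stages_run},
        "unknown_config_keys": config.unknown_keys,
        "cleanup_policy": "partial artifacts from a failed stage are left in place for inspection",
        "files": files,
    }
    out = run_dir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, default=str))
    return out
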