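"""Config loading, strict key validation, seed fan-out, run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping, Type, TypeVar

import yaml

from .errors import ConfigError

__all__ = ["load_config", "build_dataclass", "derive_seed", "write_manifest"]

T = TypeVar("T")


def load_config(path) -> dict:
    """Load a YAML (or JSON, a YAML subset) config file into a dict."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return data


def build_dataclass(cls: Type[T], data: Mapping[str, Any], context: str = "") -> T:
    """Instantiate a dataclass from a mapping, rejecting unknown keys by name."""
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - fields)
    if unknown:
        where = f" in {context}" if context else ""
        raise ConfigError(f"unknown config key(s){where}: {', '.join(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def derive_seed(module: str, global_seed: int) -> int:
    """Deterministic per-module seed from the global seed.

    Hash of ``module:global_seed`` truncated below 2^31, so module-level
    reproducibility is independent of execution order.
    """
    digest = hashlib.sha256(f"{module}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def config_hash(data: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(data, sort_keys=True, default=str).encode()
    ).hexdigest()


def write_manifest(out_dir, subcommand: str, config: Mapping[str, Any],
                   seed: int | None) -> Path:
    """Write the run manifest (config hash, seed, package version)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subcommand": subcommand,
        "config_sha256": config_hash(config),
        "seed": seed,
        "package_version": __version__,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
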