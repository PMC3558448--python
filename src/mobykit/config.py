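"""Per-client configuration: backend/layer selection per module.

A client configures each module independently — which access serves it,
access parameters, and any extra layers to stack (e.g. the cache) — plus the
data-engine loader switches and execution options.  Two clients can share
access code while talking to different repositories simply by pointing their
configurations at different store files.

YAML layout::

    registry: path/to/store.json        # optional: load this store
    seed: 0                             # optional: deterministic ids
    modules:
      tool:      {backend: memory, layers: [cache]}
      operation: {backend: reregister}
    data:
      loaders:
        sequence-length: {enabled: false}
    execution:
      retry_failover: true
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .backends import BACKENDS, Backend
from .data_engine import DataEngine
from .errors import SchemaError, UnknownBackend
from .execution import ExecutionEngine
from .registry import KINDS, Registry
from .store import load_registry


@dataclass
class ModuleConfig:
    backend: str = "memory"
    params: dict = field(default_factory=dict)
    layers: list[str] = field(default_factory=list)


@dataclass
class FrameworkConfig:
    registry_path: str | None = None
    seed: int | None = None
    modules: dict[str, ModuleConfig] = field(default_factory=dict)
    loaders: dict[str, bool] = field(default_factory=dict)
    retry_failover: bool = True


@dataclass
class Framework:
    registry: Registry
    data_engine: DataEngine
    execution: ExecutionEngine


def load_config(path: str | Path) -> FrameworkConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise SchemaError("configuration must be a mapping")
    modules = {}
    for kind, entry in (raw.get("modules") or {}).items():
        if kind not in KINDS:
            raise SchemaError(f"configuration names unknown module {kind!r}")
        entry = entry or {}
        modules[kind] = ModuleConfig(
            backend=entry.get("backend", "memory"),
            params=dict(entry.get("params") or {}),
            layers=list(entry.get("layers") or []),
        )
    loaders = {
        name: bool((entry or {}).get("enabled", True))
        for name, entry in ((raw.get("data") or {}).get("loaders") or {}).items()
    }
    return FrameworkConfig(
        registry_path=raw.get("registry"),
        seed=raw.get("seed"),
        modules=modules,
        loaders=loaders,
        retry_failover=bool((raw.get("execution") or {}).get("retry_failover", True)),
    )


def build_framework(config: FrameworkConfig) -> Framework:
    """Instantiate registry + engines exactly as the configuration dictates."""
    backends: dict[str, Backend] = {}
    for kind, module in config.modules.items():
        if module.backend not in BACKENDS:
            raise UnknownBackend(f"no backend named {module.backend!r}")
        backends[kind] = BACKENDS[module.backend](**module.params)
    if config.registry_path:
        registry = load_registry(config.registry_path, seed=config.seed, backends=backends)
    else:
        registry = Registry(seed=config.seed, backends=backends)
    for kind, module in config.modules.items():
        for layer in module.layers:
            registry.attach_layer(kind, layer)
    engine = DataEngine(registry)
    for name, enabled in config.loaders.items():
        engine.set_loader_enabled(name, enabled)
    execution = ExecutionEngine(registry, engine, retry_failover=config.retry_failover)
    return Framework(registry=registry, data_engine=engine, execution=execution)
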