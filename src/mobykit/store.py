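"""Registry persistence: a single versioned JSON store.

One document holds the complete registry — taxonomy, categories, namespaces,
tools (with nested operations and parameters, preserving declaration order),
locations, the persisted engine configuration (disabled loaders) and the
per-endpoint usage statistics.  ``load`` validates the document structure,
then runs taxonomy validation and the referential-integrity scan; ``save``
emits canonical JSON (sorted keys, records sorted by id) so that
load-then-save is byte-identical and stores from different backend types
compare equal.

Multi-repository client setups are represented by configuring module
instances over several store files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from .backends import Backend
from .errors import IntegrityError, SchemaError
from .records import (
    DatatypeNode,
    FunctionalCategoryNode,
    NamespaceRecord,
    OperationRecord,
    ParameterRecord,
    ToolLocationRecord,
    ToolRecord,
)
from .registry import Registry
from .taxonomy import validate_taxonomy

SCHEMA_VERSION = 1

_TOP_LEVEL_LISTS = ("datatypes", "categories", "namespaces", "tools", "locations")


def registry_to_document(registry: Registry) -> dict[str, Any]:
    doc: dict[str, Any] = {"schema_version": SCHEMA_VERSION}
    doc["datatypes"] = [
        {
            "name": n.name,
            "description": n.description,
            "is_parent": n.is_parent,
            "attributes": [list(a) for a in n.attributes],
            "has_parts": [list(p) for p in n.has_parts],
            "hasa_parts": [list(p) for p in n.hasa_parts],
        }
        for n in registry.backend("datatype").list()
    ]
    doc["categories"] = [
        {"name": n.name, "description": n.description, "parent": n.parent}
        for n in registry.backend("category").list()
    ]
    doc["namespaces"] = [
        {"name": n.name, "description": n.description, "source_note": n.source_note}
        for n in registry.backend("namespace").list()
    ]
    operations = {o.id: o for o in registry.backend("operation").list()}
    doc["tools"] = [
        {
            "id": t.id,
            "name": t.name,
            "description": t.description,
            "category_refs": list(t.category_refs),
            "operations": [
                {
                    "id": op.id,
                    "name": op.name,
                    "virtual": op.virtual,
                    "parameters": [
                        {
                            "id": p.id,
                            "name": p.name,
                            "kind": p.kind,
                            "datatype_ref": p.datatype_ref,
                            "namespace_ref": p.namespace_ref,
                            "cardinality": p.cardinality,
                        }
                        for p in op.parameters
                    ],
                }
                for op_id in t.operation_ids
                if (op := operations.get(op_id)) is not None
            ],
        }
        for t in registry.backend("tool").list()
    ]
    doc["locations"] = [
        {
            "id": l.id,
            "tool_ref": l.tool_ref,
            "protocol": l.protocol,
            "endpoint": l.endpoint,
            "host_info": dict(l.host_info),
        }
        for l in registry.backend("location").list()
    ]
    doc["engine_config"] = {"disabled_loaders": list(registry.disabled_loaders)}
    doc["statistics"] = {
        loc: dict(stats) for loc, stats in sorted(registry.statistics.items())
    }
    return doc


def dumps_registry(registry: Registry) -> str:
    return json.dumps(registry_to_document(registry), indent=2, sort_keys=True) + "\n"


def save_registry(registry: Registry, path: str | Path) -> None:
    Path(path).write_text(dumps_registry(registry), encoding="utf-8")


def _expect(condition: bool, message: str) -> None:
    if not condition:
        raise SchemaError(message)


def document_to_registry(
    doc: dict[str, Any],
    seed: int | None = None,
    backends: dict[str, Backend] | None = None,
) -> Registry:
    _expect(isinstance(doc, dict), "store document must be a JSON object")
    version = doc.get("schema_version")
    _expect(
        version == SCHEMA_VERSION,
        f"unsupported schema version {version!r} (supported: {SCHEMA_VERSION})",
    )
    for key in _TOP_LEVEL_LISTS:
        _expect(isinstance(doc.get(key), list), f"store field {key!r} must be a list")

    registry = Registry(seed=seed, backends=backends)
    try:
        for raw in doc["datatypes"]:
            registry.backend("datatype").register(
                DatatypeNode(
                    name=raw["name"],
                    description=raw.get("description", ""),
                    is_parent=raw.get("is_parent"),
                    attributes=[tuple(a) for a in raw.get("attributes", [])],
                    has_parts=[tuple(p) for p in raw.get("has_parts", [])],
                    hasa_parts=[tuple(p) for p in raw.get("hasa_parts", [])],
                )
            )
        for raw in doc["categories"]:
            registry.backend("category").register(
                FunctionalCategoryNode(
                    name=raw["name"],
                    description=raw.get("description", ""),
                    parent=raw.get("parent"),
                )
            )
        for raw in doc["namespaces"]:
            registry.backend("namespace").register(
                NamespaceRecord(
                    name=raw["name"],
                    description=raw.get("description", ""),
                    source_note=raw.get("source_note", ""),
                )
            )
        for raw in doc["tools"]:
            operations = raw.get("operations", [])
            registry.backend("tool").register(
                ToolRecord(
                    id=raw["id"],
                    name=raw["name"],
                    description=raw.get("description", ""),
                    category_refs=list(raw.get("category_refs", [])),
                    operation_ids=[op["id"] for op in operations],
                )
            )
            for op in operations:
                registry.backend("operation").register(
                    OperationRecord(
                        id=op["id"],
                        name=op["name"],
                        tool_ref=raw["id"],
                        virtual=bool(op.get("virtual", False)),
                        parameters=[
                            ParameterRecord(
                                id=p["id"],
                                name=p["name"],
                                kind=p["kind"],
                                datatype_ref=p["datatype_ref"],
                                namespace_ref=p.get("namespace_ref"),
                                cardinality=p.get("cardinality", "one"),
                            )
                            for p in op.get("parameters", [])
                        ],
                    )
                )
        for raw in doc["locations"]:
            registry.backend("location").register(
                ToolLocationRecord(
                    id=raw["id"],
                    tool_ref=raw["tool_ref"],
                    protocol=raw["protocol"],
                    endpoint=raw["endpoint"],
                    host_info=dict(raw.get("host_info", {})),
                )
            )
    except (KeyError, TypeError, AttributeError) as exc:
        raise SchemaError(f"malformed store record: {exc!r}") from exc
    registry.disabled_loaders = list(
        doc.get("engine_config", {}).get("disabled_loaders", [])
    )
    registry.statistics = {
        loc: dict(stats) for loc, stats in doc.get("statistics", {}).items()
    }

    problems = [f.message for f in validate_taxonomy(registry)]
    problems += registry.check_integrity()
    if problems:
        raise IntegrityError(
            "store fails validation: " + "; ".join(problems[:10])
        )
    return registry


def load_registry(
    path: str | Path,
    seed: int | None = None,
    backends: dict[str, Backend] | None = None,
) -> Registry:
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"store is not valid JSON: {exc}") from exc
    return document_to_registry(doc, seed=seed, backends=backends)
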