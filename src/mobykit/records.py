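"""Record types of the common metadata model.

All web-service accesses map into these records: an abstract tool groups
operations, each operation declares typed parameters, and concrete
deployments (endpoints/mirrors) are tool locations.  Taxonomy nodes
(datatypes, functional categories) and namespaces are name-keyed; the other
records carry opaque generated ids.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

PARAMETER_KINDS = ("input", "output", "secondary")
CARDINALITIES = ("one", "many")
PRIMITIVES = ("String", "Integer", "Float", "Boolean")


@dataclass
class ParameterRecord:
    id: str
    name: str
    kind: str                       # input | output | secondary
    datatype_ref: str
    namespace_ref: str | None = None
    cardinality: str = "one"        # one | many


@dataclass
class OperationRecord:
    id: str
    name: str
    tool_ref: str
    parameters: list[ParameterRecord] = field(default_factory=list)
    virtual: bool = False           # synthesized for operation-less protocols


@dataclass
class ToolRecord:
    id: str
    name: str
    description: str = ""
    category_refs: list[str] = field(default_factory=list)
    operation_ids: list[str] = field(default_factory=list)


@dataclass
class ToolLocationRecord:
    id: str
    tool_ref: str
    protocol: str                   # free tag: "biomoby", "soap", "local", ...
    endpoint: str
    host_info: dict[str, str] = field(default_factory=dict)  # opaque strings


@dataclass
class DatatypeNode:
    """A node of the shared datatype taxonomy.

    ``is_parent`` is the single IS (inheritance) edge; ``has_parts`` contain
    arrays of sub-objects (cardinality many) and ``hasa_parts`` single
    sub-objects (cardinality one).  The name is the identity.
    """

    name: str
    description: str = ""
    is_parent: str | None = None
    attributes: list[tuple[str, str]] = field(default_factory=list)   # (name, primitive)
    has_parts: list[tuple[str, str]] = field(default_factory=list)    # (part, datatype)
    hasa_parts: list[tuple[str, str]] = field(default_factory=list)

    @property
    def id(self) -> str:
        return self.name


@dataclass
class FunctionalCategoryNode:
    """A hierarchically arranged keyword annotating tools.

    The set of annotated tools is derived from ``ToolRecord.category_refs``
    at query time (single source of truth) rather than stored here.
    """

    name: str
    description: str = ""
    parent: str | None = None

    @property
    def id(self) -> str:
        return self.name


@dataclass
class NamespaceRecord:
    """A data-provenance label qualifying identifiers by source database."""

    name: str
    description: str = ""
    source_note: str = ""

    @property
    def id(self) -> str:
        return self.name


@dataclass(frozen=True)
class ParameterDescriptor:
    """One entry of a generated operation interface (enough to render a form)."""

    name: str
    kind: str
    datatype: str
    namespace: str | None
    cardinality: str


@dataclass
class DeletionReport:
    """Outcome of a delete: every removed id, plus references stripped in place."""

    removed: list[str] = field(default_factory=list)
    references_stripped: list[tuple[str, str]] = field(default_factory=list)


def record_id(record: Any) -> str:
    return record.id


def to_plain(record: Any) -> Any:
    """Recursively convert a record to JSON-serializable plain data."""
    if dataclasses.is_dataclass(record) and not isinstance(record, type):
        out = {}
        for f in dataclasses.fields(record):
            out[f.name] = to_plain(getattr(record, f.name))
        return out
    if isinstance(record, (list, tuple)):
        return [to_plain(v) for v in record]
    if isinstance(record, dict):
        return {k: to_plain(v) for k, v in record.items()}
    return record
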