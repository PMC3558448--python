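"""Interface layer: the uniform registry API over pluggable accesses.

The registry hosts one backend per module kind (datatype, category,
namespace, tool, operation, location) and exposes the common operations —
creation, listing with composable filters, retrieval, editing (native or
emulated by re-registration), cascading deletion and layer stacking.  Client
code never sees which access or how many layers serve a call.
"""

from __future__ import annotations

import dataclasses
import hashlib
import uuid
from collections import defaultdict
from typing import Any, Callable, Iterable, Sequence

from .backends import BACKENDS, LAYERS, Backend, MemoryBackend
from .errors import (
    BadKind,
    DependencyExists,
    DuplicateName,
    EmptyName,
    ImmutableField,
    NotFound,
    UnknownLayer,
    UnresolvedReference,
)
from .records import (
    CARDINALITIES,
    DeletionReport,
    OperationRecord,
    PARAMETER_KINDS,
    ParameterDescriptor,
    ParameterRecord,
    ToolLocationRecord,
    ToolRecord,
)

KINDS = ("datatype", "category", "namespace", "tool", "operation", "location")

#: Protocols whose native model has no operation concept; registering a
#: location for a tool without operations synthesizes a virtual operation.
OPERATION_LESS_PROTOCOLS = {"biomoby"}


@dataclasses.dataclass(frozen=True)
class Filter:
    """A pure, named predicate over records; filters compose by conjunction."""

    name: str
    predicate: Callable[[Any], bool]

    def __call__(self, record: Any) -> bool:
        return bool(self.predicate(record))


def name_contains(fragment: str) -> Filter:
    return Filter(f"name-contains:{fragment}", lambda r: fragment in r.name)


def in_category(category: str) -> Filter:
    return Filter(f"in-category:{category}", lambda r: category in r.category_refs)


def description_contains(fragment: str) -> Filter:
    return Filter(
        f"description-contains:{fragment}", lambda r: fragment in r.description
    )


class _IdGenerator:
    """Opaque unique ids; deterministic per kind when a seed is configured."""

    def __init__(self, seed: int | None = None) -> None:
        self._seed = seed
        self._counters: dict[str, int] = defaultdict(int)

    def next(self, kind: str, taken: Callable[[str], bool]) -> str:
        while True:
            self._counters[kind] += 1
            n = self._counters[kind]
            if self._seed is None:
                candidate = f"{kind}-{uuid.uuid4().hex[:12]}"
            else:
                digest = hashlib.sha1(
                    f"{self._seed}:{kind}:{n}".encode()
                ).hexdigest()[:10]
                candidate = f"{kind}-{n:04d}-{digest}"
            if not taken(candidate):
                return candidate


class Registry:
    """The Interface layer shared by every client.

    Parameters
    ----------
    seed:
        When given, generated ids are deterministic (hash of kind + counter),
        so fixtures are byte-reproducible.  ``None`` uses random UUIDs.
    backends:
        Optional mapping of module kind to a :class:`Backend` instance;
        kinds not named get a fresh in-memory native-edit access.
    unique_tool_names:
        Registries may optionally reject identically named tools; off by
        default (the model treats ids, not names, as identity).
    """

    def __init__(
        self,
        seed: int | None = None,
        backends: dict[str, Backend] | None = None,
        unique_tool_names: bool = False,
    ) -> None:
        self._ids = _IdGenerator(seed)
        self._backends: dict[str, Backend] = {}
        for kind in KINDS:
            backend = (backends or {}).get(kind)
            self._backends[kind] = backend if backend is not None else MemoryBackend()
        self.unique_tool_names = unique_tool_names
        self.statistics: dict[str, dict[str, float]] = {}
        self.disabled_loaders: list[str] = []

    # -- module plumbing ------------------------------------------------------

    def backend(self, kind: str) -> Backend:
        try:
            return self._backends[kind]
        except KeyError:
            raise NotFound(f"unknown module {kind!r}") from None

    def attach_layer(self, kind: str, layer_name: str) -> Backend:
        """Stack a named layer (e.g. ``"cache"``) on a module's access.

        The Interface surface is unchanged; only read/write routing differs.
        Returns the new top-of-stack layer.
        """
        if layer_name not in LAYERS:
            raise UnknownLayer(f"no layer named {layer_name!r}")
        layered = LAYERS[layer_name](self.backend(kind))
        self._backends[kind] = layered
        return layered

    def _new_id(self, kind: str) -> str:
        if kind == "parameter":  # parameters live nested inside operations
            existing = {
                p.id
                for op in self.backend("operation").list()
                for p in op.parameters
            }
            return self._ids.next(kind, existing.__contains__)
        backend = self.backend(kind)

        def taken(candidate: str) -> bool:
            try:
                backend.get(candidate)
                return True
            except NotFound:
                return False

        return self._ids.next(kind, taken)

    def _exists(self, kind: str, resource_id: str) -> bool:
        try:
            self.backend(kind).get(resource_id)
            return True
        except NotFound:
            return False

    def _require(self, kind: str, resource_id: str) -> Any:
        try:
            return self.backend(kind).get(resource_id)
        except NotFound:
            raise UnresolvedReference(
                f"unknown {kind} reference {resource_id!r}"
            ) from None

    def _write_update(self, kind: str, resource_id: str, changes: dict) -> Any:
        """Apply a field update; emulate via deregister+register when the
        access has no native edit.  The emulation is a single transaction for
        the local backends (restore on failure), eliminating the transient
        inconsistency re-registering repositories exhibit remotely."""
        backend = self.backend(kind)
        if backend.native_edit:
            return backend.update(resource_id, changes)
        old = backend.get(resource_id)
        new = dataclasses.replace(old, **changes)
        backend.deregister(resource_id)
        try:
            backend.register(new)
        except Exception:
            backend.register(old)
            raise
        return new

    # -- tool module ----------------------------------------------------------

    def new_tool(
        self,
        name: str,
        description: str = "",
        categories: Sequence[str] = (),
    ) -> ToolRecord:
        if not name:
            raise EmptyName("tool name must be non-empty")
        for category in categories:
            if not self._exists("category", category):
                raise UnresolvedReference(f"unknown category {category!r}")
        if self.unique_tool_names and any(
            t.name == name for t in self.backend("tool").list()
        ):
            raise DuplicateName(f"a tool named {name!r} already exists")
        record = ToolRecord(
            id=self._new_id("tool"),
            name=name,
            description=description,
            category_refs=list(categories),
        )
        return self.backend("tool").add(record)

    def add_operation(
        self, tool_id: str, name: str, virtual: bool = False
    ) -> OperationRecord:
        tool = self._require("tool", tool_id)
        record = OperationRecord(
            id=self._new_id("operation"), name=name, tool_ref=tool_id, virtual=virtual
        )
        self.backend("operation").add(record)
        self._write_update(
            "tool", tool_id, {"operation_ids": [*tool.operation_ids, record.id]}
        )
        return record

    def add_parameter(
        self,
        operation_id: str,
        name: str,
        kind: str,
        datatype: str,
        namespace: str | None = None,
        cardinality: str = "one",
    ) -> ParameterRecord:
        operation = self._require("operation", operation_id)
        if kind not in PARAMETER_KINDS:
            raise BadKind(f"parameter kind must be one of {PARAMETER_KINDS}, got {kind!r}")
        if cardinality not in CARDINALITIES:
            raise BadKind(f"cardinality must be one of {CARDINALITIES}, got {cardinality!r}")
        self._require("datatype", datatype)
        if namespace is not None:
            self._require("namespace", namespace)
        record = ParameterRecord(
            id=self._new_id("parameter"),
            name=name,
            kind=kind,
            datatype_ref=datatype,
            namespace_ref=namespace,
            cardinality=cardinality,
        )
        self._write_update(
            "operation", operation_id, {"parameters": [*operation.parameters, record]}
        )
        return record

    def new_tool_location(
        self,
        tool_id: str,
        protocol: str,
        endpoint: str,
        host_info: dict[str, str] | None = None,
    ) -> ToolLocationRecord:
        tool = self._require("tool", tool_id)
        record = ToolLocationRecord(
            id=self._new_id("location"),
            tool_ref=tool_id,
            protocol=protocol,
            endpoint=endpoint,
            host_info=dict(host_info or {}),
        )
        self.backend("location").add(record)
        if protocol in OPERATION_LESS_PROTOCOLS and not tool.operation_ids:
            # the protocol has no operation concept: synthesize one
            self.add_operation(tool_id, name=tool.name, virtual=True)
        return record

    # -- retrieval ------------------------------------------------------------

    def get_tool_list(self, filters: Iterable[Filter] = ()) -> list[ToolRecord]:
        tools = self.backend("tool").list()
        for flt in filters:
            tools = [t for t in tools if flt(t)]
        return tools

    def get_locations(self, tool_id: str) -> list[ToolLocationRecord]:
        self._require("tool", tool_id)
        return [l for l in self.backend("location").list() if l.tool_ref == tool_id]

    def get_operations(self, tool_id: str) -> list[OperationRecord]:
        tool = self._require("tool", tool_id)
        return [self.backend("operation").get(i) for i in tool.operation_ids]

    def get_resource(self, kind: str, resource_id: str) -> Any:
        return self.backend(kind).get(resource_id)

    def generate_interface(self, operation_id: str) -> list[ParameterDescriptor]:
        """Parameter descriptors, in declaration order, for rendering a form."""
        operation = self.backend("operation").get(operation_id)
        return [
            ParameterDescriptor(
                name=p.name,
                kind=p.kind,
                datatype=p.datatype_ref,
                namespace=p.namespace_ref,
                cardinality=p.cardinality,
            )
            for p in operation.parameters
        ]

    # -- editing --------------------------------------------------------------

    def update_resource(self, kind: str, resource_id: str, changes: dict) -> Any:
        record = self.backend(kind).get(resource_id)
        name_keyed = kind in ("datatype", "category", "namespace")
        if "id" in changes or (name_keyed and "name" in changes):
            raise ImmutableField("the record id cannot be changed")
        if not changes:
            return record  # identity update: no backend write
        field_names = {f.name for f in dataclasses.fields(record)}
        for key in changes:
            if key not in field_names:
                raise UnknownField(f"{type(record).__name__} has no field {key!r}")
        return self._write_update(kind, resource_id, changes)

    # -- deletion with cascade ------------------------------------------------

    def delete_resource(
        self, kind: str, resource_id: str, cascade: bool = False
    ) -> DeletionReport:
        """Delete a resource.

        With ``cascade=True`` every transitive dependent is removed and the
        report lists all removed ids; in-place references that merely point
        at the resource (category annotations, container parts) are stripped
        and reported separately.  With ``cascade=False`` the deletion is
        rejected while dependents exist.
        """
        self.backend(kind).get(resource_id)  # NotFound if absent
        handler = {
            "datatype": self._delete_datatype,
            "category": self._delete_category,
            "namespace": self._delete_namespace,
            "tool": self._delete_tool,
            "operation": self._delete_operation,
            "location": self._delete_location,
        }[kind]
        return handler(resource_id, cascade)

    def _datatype_descendants(self, name: str) -> list[str]:
        children = defaultdict(list)
        for node in self.backend("datatype").list():
            if node.is_parent is not None:
                children[node.is_parent].append(node.name)
        out: list[str] = []
        stack = [name]
        while stack:
            for child in children[stack.pop()]:
                out.append(child)
                stack.append(child)
        return sorted(out)

    def _category_descendants(self, name: str) -> list[str]:
        children = defaultdict(list)
        for node in self.backend("category").list():
            if node.parent is not None:
                children[node.parent].append(node.name)
        out: list[str] = []
        stack = [name]
        while stack:
            for child in children[stack.pop()]:
                out.append(child)
                stack.append(child)
        return sorted(out)

    def _params_referencing(self, field: str, names: set[str]):
        for operation in self.backend("operation").list():
            for param in operation.parameters:
                if getattr(param, field) in names:
                    yield operation, param

    def _strip_params(self, doomed_param_ids: set[str]) -> None:
        for operation in self.backend("operation").list():
            kept = [p for p in operation.parameters if p.id not in doomed_param_ids]
            if len(kept) != len(operation.parameters):
                self._write_update("operation", operation.id, {"parameters": kept})

    def _delete_datatype(self, name: str, cascade: bool) -> DeletionReport:
        doomed = {name, *self._datatype_descendants(name)}
        dep_params = list(self._params_referencing("datatype_ref", doomed))
        part_holders = []
        for node in self.backend("datatype").list():
            if node.name in doomed:
                continue
            if any(dt in doomed for _, dt in node.has_parts) or any(
                dt in doomed for _, dt in node.hasa_parts
            ):
                part_holders.append(node)
        dependents = (
            sorted(doomed - {name})
            + [p.id for _, p in dep_params]
            + [n.name for n in part_holders]
        )
        if not cascade and dependents:
            raise DependencyExists(
                f"datatype {name!r} has dependents", tuple(dependents)
            )
        report = DeletionReport()
        self._strip_params({p.id for _, p in dep_params})
        for node in part_holders:
            changes = {
                "has_parts": [(n, dt) for n, dt in node.has_parts if dt not in doomed],
                "hasa_parts": [(n, dt) for n, dt in node.hasa_parts if dt not in doomed],
            }
            self._write_update("datatype", node.name, changes)
            report.references_stripped.append((node.name, "parts"))
        for dt in sorted(doomed):
            self.backend("datatype").delete(dt)
        report.removed = sorted(doomed) + sorted(p.id for _, p in dep_params)
        return report

    def _delete_category(self, name: str, cascade: bool) -> DeletionReport:
        doomed = {name, *self._category_descendants(name)}
        annotated = [
            t for t in self.backend("tool").list() if set(t.category_refs) & doomed
        ]
        dependents = sorted(doomed - {name}) + [t.id for t in annotated]
        if not cascade and dependents:
            raise DependencyExists(
                f"category {name!r} has dependents", tuple(dependents)
            )
        report = DeletionReport()
        for tool in annotated:
            kept = [c for c in tool.category_refs if c not in doomed]
            self._write_update("tool", tool.id, {"category_refs": kept})
            report.references_stripped.append((tool.id, "category_refs"))
        for cat in sorted(doomed):
            self.backend("category").delete(cat)
        report.removed = sorted(doomed)
        return report

    def _delete_namespace(self, name: str, cascade: bool) -> DeletionReport:
        dep_params = list(self._params_referencing("namespace_ref", {name}))
        if not cascade and dep_params:
            raise DependencyExists(
                f"namespace {name!r} has dependents",
                tuple(p.id for _, p in dep_params),
            )
        self._strip_params({p.id for _, p in dep_params})
        self.backend("namespace").delete(name)
        return DeletionReport(removed=[name] + sorted(p.id for _, p in dep_params))

    def _delete_tool(self, tool_id: str, cascade: bool) -> DeletionReport:
        tool = self.backend("tool").get(tool_id)
        locations = [
            l for l in self.backend("location").list() if l.tool_ref == tool_id
        ]
        dependents = list(tool.operation_ids) + [l.id for l in locations]
        if not cascade and dependents:
            raise DependencyExists(f"tool {tool_id!r} has dependents", tuple(dependents))
        removed = [tool_id]
        for op_id in tool.operation_ids:
            operation = self.backend("operation").get(op_id)
            removed.append(op_id)
            removed.extend(p.id for p in operation.parameters)
            self.backend("operation").delete(op_id)
        for location in locations:
            removed.append(location.id)
            self.backend("location").delete(location.id)
            self.statistics.pop(location.id, None)
        self.backend("tool").delete(tool_id)
        return DeletionReport(removed=removed)

    def _delete_operation(self, operation_id: str, cascade: bool) -> DeletionReport:
        operation = self.backend("operation").get(operation_id)
        report = DeletionReport(
            removed=[operation_id] + [p.id for p in operation.parameters]
        )
        if self._exists("tool", operation.tool_ref):
            tool = self.backend("tool").get(operation.tool_ref)
            kept = [i for i in tool.operation_ids if i != operation_id]
            self._write_update("tool", tool.id, {"operation_ids": kept})
            report.references_stripped.append((tool.id, "operation_ids"))
        self.backend("operation").delete(operation_id)
        return report

    def _delete_location(self, location_id: str, cascade: bool) -> DeletionReport:
        self.backend("location").delete(location_id)
        self.statistics.pop(location_id, None)
        return DeletionReport(removed=[location_id])

    # -- integrity ------------------------------------------------------------

    def check_integrity(self) -> list[str]:
        """Full-scan referential integrity check; empty list iff consistent."""
        findings: list[str] = []
        datatypes = {n.name for n in self.backend("datatype").list()}
        categories = {n.name for n in self.backend("category").list()}
        namespaces = {n.name for n in self.backend("namespace").list()}
        tools = {t.id: t for t in self.backend("tool").list()}
        operations = {o.id: o for o in self.backend("operation").list()}

        for node in self.backend("datatype").list():
            if node.is_parent is not None and node.is_parent not in datatypes:
                findings.append(f"datatype {node.name}: dangling parent {node.is_parent}")
            for part, dt in [*node.has_parts, *node.hasa_parts]:
                if dt not in datatypes:
                    findings.append(f"datatype {node.name}: part {part} -> missing {dt}")
        for node in self.backend("category").list():
            if node.parent is not None and node.parent not in categories:
                findings.append(f"category {node.name}: dangling parent {node.parent}")
        for tool in tools.values():
            for cat in tool.category_refs:
                if cat not in categories:
                    findings.append(f"tool {tool.id}: dangling category {cat}")
            for op_id in tool.operation_ids:
                if op_id not in operations:
                    findings.append(f"tool {tool.id}: dangling operation {op_id}")
        for operation in operations.values():
            if operation.tool_ref not in tools:
                findings.append(f"operation {operation.id}: dangling tool {operation.tool_ref}")
            for param in operation.parameters:
                if param.datatype_ref not in datatypes:
                    findings.append(
                        f"parameter {param.id}: dangling datatype {param.datatype_ref}"
                    )
                if param.namespace_ref is not None and param.namespace_ref not in namespaces:
                    findings.append(
                        f"parameter {param.id}: dangling namespace {param.namespace_ref}"
                    )
        for location in self.backend("location").list():
            if location.tool_ref not in tools:
                findings.append(f"location {location.id}: dangling tool {location.tool_ref}")
        return findings
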