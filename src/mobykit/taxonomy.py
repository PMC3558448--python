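"""Shared datatype taxonomy, functional-category hierarchy and namespaces.

The datatype taxonomy follows the object-oriented BioMOBY model: each node
has at most one IS (inheritance) parent, primitive attributes, HAS parts
(arrays of sub-objects) and HASA parts (single sub-objects).  Declaring that
a service parameter carries a datatype guarantees the service processes that
type *and every IS-descendant*; subtype checking therefore uses IS edges
only — containment never confers substitutability.

Effective attributes/parts of a node are its own plus everything inherited
along the IS chain (ancestor-first).  A child redeclaring an inherited
attribute name is rejected (shadowing would make the effective set ambiguous).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .errors import (
    CycleError,
    DuplicateName,
    NotFound,
    UnresolvedReference,
    ValidationError,
)
from .records import (
    DatatypeNode,
    FunctionalCategoryNode,
    NamespaceRecord,
    PRIMITIVES,
    ToolRecord,
)
from .registry import Registry


@dataclass
class DatatypeView:
    """A datatype with its inherited structure materialized (ancestor-first)."""

    name: str
    description: str
    is_parent: str | None
    attributes: list[tuple[str, str]]
    has_parts: list[tuple[str, str]]
    hasa_parts: list[tuple[str, str]]
    effective_attributes: list[tuple[str, str]]
    effective_has_parts: list[tuple[str, str]]
    effective_hasa_parts: list[tuple[str, str]]


@dataclass
class Finding:
    """One taxonomy-validation problem."""

    code: str                      # cycle | dangling-parent | dangling-part |
    message: str                   # shadowed-attribute | bad-primitive | duplicate-part
    members: tuple[str, ...] = ()


# ---- datatype taxonomy -------------------------------------------------------

def _ancestry(registry: Registry, name: str) -> list[str]:
    """Names from ``name`` up to its root, self first; guards against cycles."""
    chain: list[str] = []
    seen: set[str] = set()
    current: str | None = name
    while current is not None:
        if current in seen:
            raise CycleError(f"IS cycle through {current!r}")
        seen.add(current)
        chain.append(current)
        current = registry.backend("datatype").get(current).is_parent
    return chain


def ancestors_or_self(registry: Registry, name: str) -> list[str]:
    return _ancestry(registry, name)


def add_datatype(registry: Registry, node: DatatypeNode) -> DatatypeNode:
    """Insert a taxonomy node after checking every structural invariant."""
    backend = registry.backend("datatype")
    try:
        backend.get(node.name)
    except NotFound:
        pass
    else:
        raise DuplicateName(f"datatype {node.name!r} already exists")
    if node.is_parent == node.name:
        raise CycleError(f"datatype {node.name!r} cannot be its own parent")
    if node.is_parent is not None:
        try:
            backend.get(node.is_parent)
        except NotFound:
            raise UnresolvedReference(
                f"unknown parent datatype {node.is_parent!r}"
            ) from None
    for part, dt in [*node.has_parts, *node.hasa_parts]:
        if dt != node.name:
            try:
                backend.get(dt)
            except NotFound:
                raise UnresolvedReference(
                    f"part {part!r} references unknown datatype {dt!r}"
                ) from None
    seen_attrs: set[str] = set()
    for attr, primitive in node.attributes:
        if primitive not in PRIMITIVES:
            raise ValidationError(
                f"attribute {attr!r}: primitive must be one of {PRIMITIVES}"
            )
        if attr in seen_attrs:
            raise ValidationError(f"attribute {attr!r} declared twice")
        seen_attrs.add(attr)
    if node.is_parent is not None:
        inherited = {
            a for anc in _ancestry(registry, node.is_parent)
            for a, _ in backend.get(anc).attributes
        }
        shadowed = seen_attrs & inherited
        if shadowed:
            raise ValidationError(
                f"attributes {sorted(shadowed)} shadow inherited declarations"
            )
    return backend.add(node)


def get_datatype(registry: Registry, name: str) -> DatatypeView:
    """The node plus materialized inherited attributes and parts."""
    backend = registry.backend("datatype")
    node = backend.get(name)
    eff_attrs: list[tuple[str, str]] = []
    eff_has: list[tuple[str, str]] = []
    eff_hasa: list[tuple[str, str]] = []
    for ancestor in reversed(_ancestry(registry, name)):  # root first
        anc = backend.get(ancestor)
        eff_attrs.extend(anc.attributes)
        eff_has.extend(anc.has_parts)
        eff_hasa.extend(anc.hasa_parts)
    return DatatypeView(
        name=node.name,
        description=node.description,
        is_parent=node.is_parent,
        attributes=list(node.attributes),
        has_parts=list(node.has_parts),
        hasa_parts=list(node.hasa_parts),
        effective_attributes=eff_attrs,
        effective_has_parts=eff_has,
        effective_hasa_parts=eff_hasa,
    )


def is_subtype_of(registry: Registry, child: str, ancestor: str) -> bool:
    """True iff ``ancestor`` is reachable from ``child`` via IS edges (reflexive)."""
    registry.backend("datatype").get(ancestor)  # NotFound if unknown
    return ancestor in _ancestry(registry, child)


def get_children(registry: Registry, name: str) -> list:
    """Direct children of a datatype or functional category node."""
    try:
        registry.backend("datatype").get(name)
    except NotFound:
        registry.backend("category").get(name)
        return [
            n for n in registry.backend("category").list() if n.parent == name
        ]
    return [
        n for n in registry.backend("datatype").list() if n.is_parent == name
    ]


def get_datatype_roots(registry: Registry) -> list[DatatypeNode]:
    return [n for n in registry.backend("datatype").list() if n.is_parent is None]


def reparent(registry: Registry, name: str, new_parent: str | None):
    """Move a datatype or category under a new parent; subtype relations change."""
    try:
        registry.backend("datatype").get(name)
        kind, parent_field = "datatype", "is_parent"
    except NotFound:
        registry.backend("category").get(name)
        kind, parent_field = "category", "parent"
    if new_parent is not None:
        registry.backend(kind).get(new_parent)
        # walking up from the new parent must never reach the node itself
        current: str | None = new_parent
        seen: set[str] = set()
        while current is not None:
            if current == name:
                raise CycleError(
                    f"reparenting {name!r} under {new_parent!r} creates a cycle"
                )
            if current in seen:
                raise CycleError(f"existing cycle through {current!r}")
            seen.add(current)
            current = getattr(registry.backend(kind).get(current), parent_field)
    node = registry.backend(kind).get(name)
    if getattr(node, parent_field) == new_parent:
        return node  # no-op
    return registry.update_resource(kind, name, {parent_field: new_parent})


def validate_taxonomy(registry: Registry) -> list[Finding]:
    """Full validation report; an empty report means all invariants hold."""
    findings: list[Finding] = []
    backend = registry.backend("datatype")
    nodes = {n.name: n for n in backend.list()}

    # cycles (IS graph must be a forest)
    state: dict[str, int] = {}
    for start in sorted(nodes):
        if state.get(start):
            continue
        path: list[str] = []
        current: str | None = start
        while current is not None and current in nodes:
            if state.get(current) == 2:
                break
            if current in path:
                cycle = path[path.index(current):]
                findings.append(
                    Finding("cycle", f"IS cycle: {' -> '.join(cycle)}", tuple(cycle))
                )
                break
            path.append(current)
            current = nodes[current].is_parent
        for visited in path:
            state[visited] = 2

    cyclic = {m for f in findings for m in f.members}
    for node in backend.list():
        if node.is_parent is not None and node.is_parent not in nodes:
            findings.append(
                Finding(
                    "dangling-parent",
                    f"datatype {node.name}: parent {node.is_parent} missing",
                    (node.name, node.is_parent),
                )
            )
        seen_parts: set[str] = set()
        for part, dt in [*node.has_parts, *node.hasa_parts]:
            if dt not in nodes:
                findings.append(
                    Finding(
                        "dangling-part",
                        f"datatype {node.name}: part {part} -> missing {dt}",
                        (node.name, part, dt),
                    )
                )
            if part in seen_parts:
                findings.append(
                    Finding(
                        "duplicate-part",
                        f"datatype {node.name}: part name {part} repeated",
                        (node.name, part),
                    )
                )
            seen_parts.add(part)
        for attr, primitive in node.attributes:
            if primitive not in PRIMITIVES:
                findings.append(
                    Finding(
                        "bad-primitive",
                        f"datatype {node.name}: attribute {attr} has primitive {primitive}",
                        (node.name, attr),
                    )
                )
        # shadowing along the lineage (skip nodes on a cycle)
        if node.name not in cyclic and node.is_parent in nodes:
            try:
                lineage = _ancestry(registry, node.is_parent)
            except CycleError:
                lineage = []
            inherited = {a for anc in lineage for a, _ in nodes[anc].attributes}
            for attr, _ in node.attributes:
                if attr in inherited:
                    findings.append(
                        Finding(
                            "shadowed-attribute",
                            f"datatype {node.name}: attribute {attr} shadows an ancestor",
                            (node.name, attr),
                        )
                    )
    return findings


# ---- functional categories ---------------------------------------------------

def add_category(
    registry: Registry, name: str, description: str = "", parent: str | None = None
) -> FunctionalCategoryNode:
    backend = registry.backend("category")
    try:
        backend.get(name)
    except NotFound:
        pass
    else:
        raise DuplicateName(f"category {name!r} already exists")
    if parent == name:
        raise CycleError(f"category {name!r} cannot be its own parent")
    if parent is not None:
        try:
            backend.get(parent)
        except NotFound:
            raise UnresolvedReference(f"unknown parent category {parent!r}") from None
    return backend.add(FunctionalCategoryNode(name, description, parent))


def get_category_roots(registry: Registry) -> list[FunctionalCategoryNode]:
    return [n for n in registry.backend("category").list() if n.parent is None]


def category_descendants(registry: Registry, name: str) -> list[str]:
    children = defaultdict(list)
    for node in registry.backend("category").list():
        if node.parent is not None:
            children[node.parent].append(node.name)
    out: list[str] = []
    stack = [name]
    while stack:
        for child in children[stack.pop()]:
            out.append(child)
            stack.append(child)
    return sorted(out)


def get_tools_for_category(
    registry: Registry, category: str, recursive: bool = False
) -> list[ToolRecord]:
    registry.backend("category").get(category)
    wanted = {category}
    if recursive:
        wanted.update(category_descendants(registry, category))
    return [
        t for t in registry.backend("tool").list() if set(t.category_refs) & wanted
    ]


# ---- namespaces --------------------------------------------------------------

def add_namespace(
    registry: Registry, name: str, description: str = "", source_note: str = ""
) -> NamespaceRecord:
    backend = registry.backend("namespace")
    try:
        backend.get(name)
    except NotFound:
        pass
    else:
        raise DuplicateName(f"namespace {name!r} already exists")
    return backend.add(NamespaceRecord(name, description, source_note))
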