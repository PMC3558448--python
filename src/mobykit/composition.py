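"""Compatibility search and automatic pipeline discovery.

Nodes of the search space are datatypes; every (operation, input parameter,
output parameter) triple is a directed edge whose tail is not a single node
but an *acceptance set* — the edge accepts any datatype that is an
IS-subtype of the declared input datatype, exactly as the services
themselves do.  A pipeline is an ordered chain of such edges where each
delivered datatype is a subtype of the next declared input.

``find_path`` returns a shortest pipeline (fewest operations) with a
deterministic tie-break (lexicographically smallest sequence of
(tool name, operation name) pairs).  Secondary parameters are fine-tune
settings and never participate in linking; mandatory inputs of a stage that
the chain does not feed are reported as ``unresolved_inputs`` for the client
to collect from the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import BadKind, NoPath
from .records import OperationRecord
from .registry import Registry
from .taxonomy import is_subtype_of

DEFAULT_MAX_DEPTH = 6


@dataclass(frozen=True)
class CompatibilityEdge:
    """One typed link offered by an operation: consumes one input parameter,
    produces one output parameter."""

    operation_id: str
    tool_name: str
    operation_name: str
    input_param: str
    input_datatype: str
    output_param: str
    output_datatype: str

    @property
    def sort_key(self) -> tuple[str, str, str, str]:
        return (self.tool_name, self.operation_name, self.input_param, self.output_param)


@dataclass(frozen=True)
class PipelineStage:
    operation_id: str
    tool_name: str
    operation_name: str
    input_param: str
    output_param: str
    link_datatype: str  # the datatype delivered into this stage


@dataclass
class Pipeline:
    source: str
    target: str
    stages: list[PipelineStage] = field(default_factory=list)
    unresolved_inputs: list[tuple[str, str]] = field(default_factory=list)  # (op id, param)

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def name_sequence(self) -> tuple[tuple[str, str], ...]:
        return tuple((s.tool_name, s.operation_name) for s in self.stages)


def compatibility_edges(registry: Registry) -> list[CompatibilityEdge]:
    """All (operation, input, output) edges, deterministically ordered."""
    tools = {t.id: t for t in registry.backend("tool").list()}
    edges: list[CompatibilityEdge] = []
    for operation in registry.backend("operation").list():
        tool = tools.get(operation.tool_ref)
        if tool is None:
            continue
        inputs = [p for p in operation.parameters if p.kind == "input"]
        outputs = [p for p in operation.parameters if p.kind == "output"]
        for inp in inputs:
            for out in outputs:
                edges.append(
                    CompatibilityEdge(
                        operation_id=operation.id,
                        tool_name=tool.name,
                        operation_name=operation.name,
                        input_param=inp.name,
                        input_datatype=inp.datatype_ref,
                        output_param=out.name,
                        output_datatype=out.datatype_ref,
                    )
                )
    edges.sort(key=lambda e: e.sort_key)
    return edges


def find_consumers(registry: Registry, datatype: str) -> list[OperationRecord]:
    """Operations with at least one input accepting the datatype (subtype rule)."""
    registry.backend("datatype").get(datatype)
    out = []
    for operation in registry.backend("operation").list():
        if any(
            p.kind == "input" and is_subtype_of(registry, datatype, p.datatype_ref)
            for p in operation.parameters
        ):
            out.append(operation)
    return out


def find_producers(registry: Registry, datatype: str) -> list[OperationRecord]:
    """Operations with at least one output delivering the datatype or a subtype."""
    registry.backend("datatype").get(datatype)
    out = []
    for operation in registry.backend("operation").list():
        if any(
            p.kind == "output" and is_subtype_of(registry, p.datatype_ref, datatype)
            for p in operation.parameters
        ):
            out.append(operation)
    return out


def _unresolved_inputs(registry: Registry, stages: list[PipelineStage]):
    unresolved: list[tuple[str, str]] = []
    for stage in stages:
        operation = registry.backend("operation").get(stage.operation_id)
        for param in operation.parameters:
            if param.kind == "input" and param.name != stage.input_param:
                unresolved.append((operation.id, param.name))
    return unresolved


def _build_pipeline(
    registry: Registry, source: str, target: str, chain: list[tuple[CompatibilityEdge, str]]
) -> Pipeline:
    stages = [
        PipelineStage(
            operation_id=edge.operation_id,
            tool_name=edge.tool_name,
            operation_name=edge.operation_name,
            input_param=edge.input_param,
            output_param=edge.output_param,
            link_datatype=incoming,
        )
        for edge, incoming in chain
    ]
    return Pipeline(
        source=source,
        target=target,
        stages=stages,
        unresolved_inputs=_unresolved_inputs(registry, stages),
    )


def find_path(
    registry: Registry, source: str, target: str, max_len: int = DEFAULT_MAX_DEPTH
) -> Pipeline:
    """A shortest type-compatible pipeline from ``source`` to ``target``.

    Level-synchronous breadth-first search over datatypes.  Within each level
    candidate paths are kept in lexicographic (tool name, operation name)
    order and only the first path reaching a datatype survives — any shortest
    path's prefix to an intermediate datatype is itself lexicographically
    minimal (continuations depend only on the datatype reached), so the first
    hit is the deterministic tie-break winner.  Raises :class:`NoPath` when
    no chain of at most ``max_len`` operations exists.
    """
    registry.backend("datatype").get(source)
    registry.backend("datatype").get(target)
    if is_subtype_of(registry, source, target):
        return Pipeline(source=source, target=target)  # already satisfied

    edges = compatibility_edges(registry)
    visited = {source}
    frontier: list[tuple[str, list[tuple[CompatibilityEdge, str]]]] = [(source, [])]
    for _depth in range(max_len):
        hits: list[list[tuple[CompatibilityEdge, str]]] = []
        next_frontier: list[tuple[str, list[tuple[CompatibilityEdge, str]]]] = []
        claimed: set[str] = set()
        for datatype, chain in frontier:
            for edge in edges:
                if not is_subtype_of(registry, datatype, edge.input_datatype):
                    continue
                new_chain = chain + [(edge, datatype)]
                if is_subtype_of(registry, edge.output_datatype, target):
                    hits.append(new_chain)
                produced = edge.output_datatype
                if produced not in visited and produced not in claimed:
                    claimed.add(produced)
                    next_frontier.append((produced, new_chain))
        if hits:
            return _build_pipeline(registry, source, target, hits[0])
        visited |= claimed
        frontier = next_frontier
        if not frontier:
            break
    raise NoPath(
        f"no pipeline from {source!r} to {target!r} within {max_len} operations"
    )


def enumerate_paths(
    registry: Registry, source: str, target: str, max_len: int
) -> list[Pipeline]:
    """Every distinct valid pipeline of at most ``max_len`` stages, sorted by
    (length, lexicographic tool-name sequence).  Includes the empty pipeline
    when the source already satisfies the target."""
    if max_len < 1:
        raise BadKind("max_len must be at least 1")
    registry.backend("datatype").get(source)
    registry.backend("datatype").get(target)
    edges = compatibility_edges(registry)
    found: list[list[tuple[CompatibilityEdge, str]]] = []
    if is_subtype_of(registry, source, target):
        found.append([])

    def extend(datatype: str, chain: list[tuple[CompatibilityEdge, str]]) -> None:
        if len(chain) == max_len:
            return
        for edge in edges:
            if not is_subtype_of(registry, datatype, edge.input_datatype):
                continue
            new_chain = chain + [(edge, datatype)]
            if is_subtype_of(registry, edge.output_datatype, target):
                found.append(new_chain)
            extend(edge.output_datatype, new_chain)

    extend(source, [])
    pipelines = [_build_pipeline(registry, source, target, chain) for chain in found]
    seen: set[tuple] = set()
    unique: list[Pipeline] = []
    for p in pipelines:
        key = tuple(
            (s.operation_id, s.input_param, s.output_param) for s in p.stages
        )
        if key not in seen:
            seen.add(key)
            unique.append(p)
    unique.sort(
        key=lambda p: (
            len(p),
            p.name_sequence,
            tuple((s.input_param, s.output_param) for s in p.stages),
        )
    )
    return unique


def validate_pipeline(registry: Registry, pipeline: Pipeline) -> bool:
    """Re-check every type-link invariant independently of how the pipeline
    was found; raises :class:`NoPath` on the first violated link."""
    current = pipeline.source
    for index, stage in enumerate(pipeline.stages, start=1):
        operation = registry.backend("operation").get(stage.operation_id)
        inp = next(
            (p for p in operation.parameters
             if p.name == stage.input_param and p.kind == "input"),
            None,
        )
        out = next(
            (p for p in operation.parameters
             if p.name == stage.output_param and p.kind == "output"),
            None,
        )
        if inp is None or out is None:
            raise NoPath(f"stage {index}: parameters not declared by the operation")
        if not is_subtype_of(registry, current, inp.datatype_ref):
            raise NoPath(
                f"stage {index}: {current!r} is not a subtype of {inp.datatype_ref!r}"
            )
        if stage.link_datatype != current:
            raise NoPath(f"stage {index}: recorded link datatype disagrees")
        current = out.datatype_ref
    if not is_subtype_of(registry, current, pipeline.target):
        raise NoPath(
            f"final datatype {current!r} does not satisfy target {pipeline.target!r}"
        )
    return True
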