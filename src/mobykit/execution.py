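"""Workers, the task lifecycle and pipeline enactment.

Tools are invoked through protocol-specific plug-ins (*workers*).  A task
records one invocation: its inputs, the endpoint used, a strict status
machine (SUBMITTED -> RUNNING -> SUCCEEDED | FAILED, audited via an event
log) and, on success, the results.  Workers run synchronously in-process;
the reference-passing three-step lifecycle of remote deployments (submit,
poll, retrieve) is modeled by the same API — clients poll ``get_status``
and then call ``get_results``.

A worker that declares a wire format (e.g. the BioMOBY mock demands
``moby-xml``) triggers automatic data adaptation: structured inputs are run
through the in-scope loaders and serialized before invocation, and outputs
are parsed back into typed trees.  Endpoint mirrors are chosen round-robin,
with an optional single retry on the next mirror after a failure, and every
invocation feeds the per-endpoint usage statistics.
"""

from __future__ import annotations

import time
import uuid
from dataclasses import dataclass, field
from enum import Enum
from typing import Any

from .composition import Pipeline
from .data_engine import DataEngine, StructuredData
from .errors import (
    DuplicateProtocol,
    IllegalTransition,
    MissingInput,
    NoLocation,
    NotFinished,
    NotFound,
    NoWorker,
    StageFailed,
    TypeMismatch,
)
from .records import OperationRecord, ToolLocationRecord
from .registry import Registry
from .taxonomy import is_subtype_of


class TaskStatus(str, Enum):
    SUBMITTED = "SUBMITTED"
    RUNNING = "RUNNING"
    SUCCEEDED = "SUCCEEDED"
    FAILED = "FAILED"


_LEGAL_TRANSITIONS = {
    (TaskStatus.SUBMITTED, TaskStatus.RUNNING),
    (TaskStatus.RUNNING, TaskStatus.SUCCEEDED),
    (TaskStatus.RUNNING, TaskStatus.FAILED),
}


@dataclass
class Task:
    """One tool invocation with its full status history."""

    id: str
    location_ref: str
    operation_ref: str
    inputs: dict[str, Any]
    status: TaskStatus = TaskStatus.SUBMITTED
    results: dict[str, Any] | None = None
    error: dict[str, str] | None = None
    created: float = field(default_factory=time.time)
    started: float | None = None
    finished: float | None = None
    events: list[tuple[float, str, str]] = field(default_factory=list)

    def transition(self, new_status: TaskStatus) -> None:
        if (self.status, new_status) not in _LEGAL_TRANSITIONS:
            raise IllegalTransition(f"{self.status.value} -> {new_status.value}")
        self.events.append((time.time(), self.status.value, new_status.value))
        self.status = new_status
        if new_status is TaskStatus.RUNNING:
            self.started = time.time()
        elif new_status in (TaskStatus.SUCCEEDED, TaskStatus.FAILED):
            self.finished = time.time()


@dataclass
class StatRecord:
    """Usage statistics for one endpoint (mirror)."""

    location_ref: str
    count: int = 0
    success: int = 0
    latency: float = 0.0


class Worker:
    """Protocol plug-in contract.

    ``wire_format`` of ``None`` means the worker exchanges structured data
    directly; a format id (e.g. ``"moby-xml"``) makes the engine serialize
    inputs and parse outputs around the call.
    """

    protocol: str = ""
    wire_format: str | None = None
    may_pass_by_reference: bool = False

    def invoke(
        self,
        location: ToolLocationRecord,
        operation: OperationRecord,
        inputs: dict[str, Any],
    ) -> dict[str, Any]:
        raise NotImplementedError


class LocalEchoWorker(Worker):
    """Returns its inputs unchanged; the minimal local protocol."""

    protocol = "local"

    def invoke(self, location, operation, inputs):
        return dict(inputs)


class CallableWorker(Worker):
    """Adapts a plain callable ``fn(location, operation, inputs) -> outputs``."""

    def __init__(self, protocol: str, fn, wire_format: str | None = None):
        self.protocol = protocol
        self.wire_format = wire_format
        self._fn = fn

    def invoke(self, location, operation, inputs):
        return self._fn(location, operation, inputs)


class MockBiomobyWorker(Worker):
    """Offline stand-in for a BioMOBY endpoint (synthetic: no network I/O).

    Dispatches on the operation name to canned handlers that receive and
    return moby-xml bytes, mimicking a service that answers in the BioMOBY
    wire dialect.
    """

    protocol = "biomoby"
    wire_format = "moby-xml"

    def __init__(self, handlers: dict[str, Any]):
        self.handlers = handlers

    def invoke(self, location, operation, inputs):
        handler = self.handlers.get(operation.name)
        if handler is None:
            raise NoWorker(f"no canned handler for operation {operation.name!r}")
        return handler(operation, inputs)


@dataclass
class EnactmentResult:
    data: StructuredData
    results: dict[str, Any]
    tasks: list[Task] = field(default_factory=list)


class ExecutionEngine:
    """Task lifecycle manager bound to one registry and data engine."""

    def __init__(
        self,
        registry: Registry,
        data_engine: DataEngine | None = None,
        retry_failover: bool = True,
    ) -> None:
        self.registry = registry
        self.data_engine = data_engine or DataEngine(registry)
        self.retry_failover = retry_failover
        self.workers: dict[str, Worker] = {}
        self.tasks: dict[str, Task] = {}
        self._round_robin: dict[str, int] = {}

    # -- workers ---------------------------------------------------------------

    def register_worker(self, worker: Worker) -> str:
        if not worker.protocol:
            raise NoWorker("worker must declare a non-empty protocol tag")
        if worker.protocol in self.workers:
            raise DuplicateProtocol(
                f"a worker for protocol {worker.protocol!r} is already registered"
            )
        self.workers[worker.protocol] = worker
        return worker.protocol

    # -- statistics --------------------------------------------------------------

    def _record_stats(self, location_id: str, ok: bool, elapsed: float) -> None:
        stats = self.registry.statistics.setdefault(
            location_id, {"count": 0, "success": 0, "latency": 0.0}
        )
        stats["count"] += 1
        stats["success"] += 1 if ok else 0
        stats["latency"] += elapsed

    def get_statistics(self, location_id: str | None = None) -> list[StatRecord]:
        def record(loc_id: str) -> StatRecord:
            stats = self.registry.statistics.get(
                loc_id, {"count": 0, "success": 0, "latency": 0.0}
            )
            return StatRecord(
                location_ref=loc_id,
                count=int(stats["count"]),
                success=int(stats["success"]),
                latency=float(stats["latency"]),
            )

        if location_id is not None:
            self.registry.backend("location").get(location_id)  # NotFound if absent
            return [record(location_id)]
        return [record(l.id) for l in self.registry.backend("location").list()]

    # -- task lifecycle ------------------------------------------------------------

    def add_task(
        self, location_id: str, operation_id: str, inputs: dict[str, Any]
    ) -> Task:
        """Create a task and invoke the worker for the location's protocol.

        Mandatory inputs must all be present and structured inputs must carry
        a subtype of the declared parameter datatype — services accept data
        instances of subtypes of their declared inputs.
        """
        location = self.registry.backend("location").get(location_id)
        operation = self.registry.backend("operation").get(operation_id)
        worker = self.workers.get(location.protocol)
        if worker is None:
            raise NoWorker(f"no worker registered for protocol {location.protocol!r}")
        for param in operation.parameters:
            if param.kind == "input" and param.name not in inputs:
                raise MissingInput(f"mandatory input {param.name!r} missing")
            supplied = inputs.get(param.name)
            if isinstance(supplied, StructuredData) and not is_subtype_of(
                self.registry, supplied.datatype, param.datatype_ref
            ):
                raise TypeMismatch(
                    f"input {param.name!r}: {supplied.datatype!r} is not a "
                    f"subtype of {param.datatype_ref!r}"
                )
        task = Task(
            id=f"task-{uuid.uuid4().hex[:12]}",
            location_ref=location_id,
            operation_ref=operation_id,
            inputs=dict(inputs),
        )
        self.tasks[task.id] = task
        self._run(task, worker, location, operation)
        return task

    def _run(self, task: Task, worker: Worker, location, operation) -> None:
        task.transition(TaskStatus.RUNNING)
        t0 = time.perf_counter()
        try:
            wire_inputs = dict(task.inputs)
            if worker.wire_format is not None:
                for name, value in wire_inputs.items():
                    if isinstance(value, StructuredData):
                        loaded, _ = self.data_engine.apply_loaders(value)
                        wire_inputs[name] = self.data_engine.serialize(
                            loaded, worker.wire_format
                        )
            outputs = worker.invoke(location, operation, wire_inputs)
            if worker.wire_format is not None:
                outputs = self._parse_outputs(operation, worker.wire_format, outputs)
            task.results = outputs
            task.transition(TaskStatus.SUCCEEDED)
        except Exception as exc:
            task.error = {"type": type(exc).__name__, "message": str(exc)}
            task.transition(TaskStatus.FAILED)
        self._record_stats(
            location.id, task.status is TaskStatus.SUCCEEDED, time.perf_counter() - t0
        )

    def _parse_outputs(
        self, operation, wire_format: str, outputs: dict[str, Any]
    ) -> dict[str, Any]:
        declared = {
            p.name: p.datatype_ref for p in operation.parameters if p.kind == "output"
        }
        parsed: dict[str, Any] = {}
        for name, value in outputs.items():
            if name in declared and isinstance(value, (bytes, bytearray)):
                parsed[name] = self.data_engine.parse(
                    bytes(value), wire_format, declared[name]
                )
            else:
                parsed[name] = value
        return parsed

    def get_task(self, task_id: str) -> Task:
        try:
            return self.tasks[task_id]
        except KeyError:
            raise NotFound(f"no task with id {task_id!r}") from None

    def get_status(self, task_id: str) -> TaskStatus:
        return self.get_task(task_id).status

    def get_results(self, task_id: str) -> dict[str, Any]:
        task = self.get_task(task_id)
        if task.status is not TaskStatus.SUCCEEDED:
            raise NotFinished(
                f"task {task_id} is {task.status.value}", error=task.error
            )
        return task.results or {}

    # -- endpoint selection -----------------------------------------------------------

    def eligible_locations(self, tool_id: str) -> list[ToolLocationRecord]:
        return [
            l
            for l in self.registry.get_locations(tool_id)
            if l.protocol in self.workers
        ]

    def select_location(self, tool_id: str) -> ToolLocationRecord:
        """Round-robin over the tool's locations that have a registered worker."""
        eligible = self.eligible_locations(tool_id)
        if not eligible:
            raise NoLocation(f"tool {tool_id!r} has no invocable location")
        index = self._round_robin.get(tool_id, 0)
        self._round_robin[tool_id] = index + 1
        return eligible[index % len(eligible)]

    def invoke_operation(self, operation_id: str, inputs: dict[str, Any]) -> Task:
        """Select an endpoint and run; on failure optionally retry once on the
        next mirror (fault tolerance across endpoints)."""
        operation = self.registry.backend("operation").get(operation_id)
        task = self.add_task(self.select_location(operation.tool_ref).id, operation_id, inputs)
        if (
            task.status is TaskStatus.FAILED
            and self.retry_failover
            and len(self.eligible_locations(operation.tool_ref)) > 1
        ):
            task = self.add_task(
                self.select_location(operation.tool_ref).id, operation_id, inputs
            )
        return task

    # -- pipeline enactment --------------------------------------------------------------

    def enact_pipeline(
        self,
        pipeline: Pipeline,
        initial: StructuredData,
        extra_inputs: dict[str, Any] | None = None,
    ) -> EnactmentResult:
        """Run a discovered pipeline end to end.

        Each stage receives the previous stage's output (checked to be a
        subtype of the declared input; adapted through loaders/formatters by
        the worker wire-format machinery), plus any ``extra_inputs`` covering
        the stage's unresolved mandatory inputs.  Aborts on the first failed
        stage.
        """
        extra_inputs = dict(extra_inputs or {})
        current = initial
        tasks: list[Task] = []
        results: dict[str, Any] = {}
        for index, stage in enumerate(pipeline.stages, start=1):
            operation = self.registry.backend("operation").get(stage.operation_id)
            if not is_subtype_of(self.registry, current.datatype, _input_datatype(operation, stage.input_param)):
                raise StageFailed(
                    index,
                    TypeMismatch(
                        f"{current.datatype!r} does not satisfy the declared input"
                    ),
                )
            inputs: dict[str, Any] = {stage.input_param: current}
            for param in operation.parameters:
                if param.kind == "input" and param.name != stage.input_param:
                    key = (operation.id, param.name)
                    if key in extra_inputs:
                        inputs[param.name] = extra_inputs[key]
                    elif param.name in extra_inputs:
                        inputs[param.name] = extra_inputs[param.name]
                    else:
                        raise MissingInput(
                            f"stage {index}: unresolved input {param.name!r} not covered"
                        )
            try:
                task = self.invoke_operation(stage.operation_id, inputs)
            except NotFinished as exc:  # defensive; invoke returns a task
                raise StageFailed(index, exc) from exc
            tasks.append(task)
            if task.status is not TaskStatus.SUCCEEDED:
                raise StageFailed(
                    index, RuntimeError((task.error or {}).get("message", "failed"))
                )
            results = task.results or {}
            output = results.get(stage.output_param)
            if not isinstance(output, StructuredData):
                raise StageFailed(
                    index,
                    TypeMismatch(
                        f"stage output {stage.output_param!r} missing or untyped"
                    ),
                )
            current = output
        return EnactmentResult(data=current, results=results, tasks=tasks)


def _input_datatype(operation: OperationRecord, param_name: str) -> str:
    for param in operation.parameters:
        if param.name == param_name and param.kind == "input":
            return param.datatype_ref
    raise TypeMismatch(f"operation declares no input named {param_name!r}")


def audit_task(task: Task) -> list[str]:
    """Event-log audit: returns a finding per illegal or inconsistent transition."""
    findings: list[str] = []
    expected = TaskStatus.SUBMITTED
    for _, old, new in task.events:
        if old != expected.value:
            findings.append(f"task {task.id}: event from {old}, expected {expected.value}")
        if (TaskStatus(old), TaskStatus(new)) not in _LEGAL_TRANSITIONS:
            findings.append(f"task {task.id}: illegal transition {old} -> {new}")
        expected = TaskStatus(new)
    if task.status.value != expected.value:
        findings.append(f"task {task.id}: status {task.status.value} disagrees with log")
    if task.status in (TaskStatus.SUCCEEDED, TaskStatus.FAILED) and len(task.events) != 2:
        findings.append(f"task {task.id}: finished with {len(task.events)} events")
    if task.results is not None and task.status is not TaskStatus.SUCCEEDED:
        findings.append(f"task {task.id}: results present before SUCCEEDED")
    return findings
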