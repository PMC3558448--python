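"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import pytest

from mobykit import (
    DataEngine,
    Registry,
    build_usecase_execution,
    build_usecase_registry,
)
from mobykit.backends import MemoryBackend


class CountingBackend(MemoryBackend):
    """In-memory backend that tallies read calls (to observe cache behaviour)."""

    def __init__(self) -> None:
        super().__init__()
        self.reads = 0
        self.writes = 0

    def get(self, resource_id):
        self.reads += 1
        return super().get(resource_id)

    def list(self):
        self.reads += 1
        return super().list()

    def add(self, record):
        self.writes += 1
        return super().add(record)

    def update(self, resource_id, changes):
        self.writes += 1
        return super().update(resource_id, changes)

    def delete(self, resource_id):
        self.writes += 1
        return super().delete(resource_id)

    register = add

    def deregister(self, resource_id):
        self.writes += 1
        return super().deregister(resource_id)


@pytest.fixture
def usecase_registry() -> Registry:
    return build_usecase_registry()


@pytest.fixture
def usecase_engine(usecase_registry) -> DataEngine:
    return DataEngine(usecase_registry)


@pytest.fixture
def usecase_execution():
    return build_usecase_execution()


def random_taxonomy_registry(seed: int, n_nodes: int) -> Registry:
    """A registry holding only a seeded random taxonomy."""
    from mobykit.fixtures import generate_random_taxonomy

    registry = Registry(seed=seed)
    generate_random_taxonomy(registry, random.Random(seed), n_nodes)
    return registry


def subtype_closure_oracle(registry: Registry) -> set[tuple[str, str]]:
    """Transitive closure of IS edges, computed independently (reflexive)."""
    nodes = registry.backend("datatype").list()
    parent = {n.name: n.is_parent for n in nodes}
    closure: set[tuple[str, str]] = set()
    for name in parent:
        current: str | None = name
        while current is not None:
            closure.add((name, current))
            current = parent[current]
    return closure


def brute_force_min_path(registry: Registry, source: str, target: str,
                         max_len: int = 4) -> int | None:
    """Exhaustive enumeration of operation-edge sequences, shortest first.

    Independent of the BFS under test: plain depth-limited DFS over every
    (operation, input, output) pair using the closure oracle for typing.
    """
    closure = subtype_closure_oracle(registry)
    tools = {t.id: t for t in registry.backend("tool").list()}
    edges = []
    for op in registry.backend("operation").list():
        if op.tool_ref not in tools:
            continue
        for p_in in op.parameters:
            if p_in.kind != "input":
                continue
            for p_out in op.parameters:
                if p_out.kind != "output":
                    continue
                edges.append((p_in.datatype_ref, p_out.datatype_ref))
    if (source, target) in closure:
        return 0
    frontier = {source}
    for length in range(1, max_len + 1):
        produced = set()
        for dt in frontier:
            for in_dt, out_dt in edges:
                if (dt, in_dt) in closure:
                    produced.add(out_dt)
        if any((dt, target) in closure for dt in produced):
            return length
        frontier = frontier | produced
    return None
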