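"""Registry interface: creation, filtering, editing, cascade, layers."""

from __future__ import annotations

import random

import pytest

from mobykit import (
    Registry,
    build_usecase_registry,
    add_category,
    add_datatype,
    add_namespace,
    DatatypeNode,
    name_contains,
    in_category,
)
from mobykit.backends import CacheLayer, ReRegistrationBackend
from mobykit.errors import (
    BadKind,
    DependencyExists,
    DuplicateName,
    EmptyName,
    ImmutableField,
    NotFound,
    UnknownLayer,
    UnresolvedReference,
)
from mobykit.store import dumps_registry

from conftest import CountingBackend


def tool_by_name(registry, name):
    return next(t for t in registry.get_tool_list() if t.name == name)


class TestToolCreation:
    def test_usecase_provider_registers_two_tools(self, usecase_registry):
        names = [t.name for t in usecase_registry.get_tool_list()]
        assert names == sorted(names)
        assert set(names) == {"getAminoAcidSequence", "runRPSBlast"}

    def test_empty_name_rejected(self, usecase_registry):
        with pytest.raises(EmptyName):
            usecase_registry.new_tool("", "no name")

    def test_unknown_category_rejected(self, usecase_registry):
        with pytest.raises(UnresolvedReference):
            usecase_registry.new_tool("t", categories=["NoSuchCategory"])

    def test_tool_count_equals_successful_adds(self):
        registry = Registry(seed=1)
        add_category(registry, "C")
        for i in range(100):
            registry.new_tool(f"tool-{i:03d}", categories=["C"])
        assert len(registry.get_tool_list()) == 100

    def test_duplicate_names_allowed_unless_configured(self):
        registry = Registry(seed=0)
        registry.new_tool("same")
        registry.new_tool("same")  # ids are the identity
        strict = Registry(seed=0, unique_tool_names=True)
        strict.new_tool("same")
        with pytest.raises(DuplicateName):
            strict.new_tool("same")


class TestOperationsAndParameters:
    def test_same_operation_name_gets_distinct_ids(self, usecase_registry):
        tool = tool_by_name(usecase_registry, "runRPSBlast")
        a = usecase_registry.add_operation(tool.id, "again")
        b = usecase_registry.add_operation(tool.id, "again")
        assert a.id != b.id

    def test_add_operation_to_deleted_tool(self, usecase_registry):
        tool = tool_by_name(usecase_registry, "runRPSBlast")
        usecase_registry.delete_resource("tool", tool.id, cascade=True)
        with pytest.raises(UnresolvedReference):
            usecase_registry.add_operation(tool.id, "late")

    def test_parameter_kind_is_closed_enum(self, usecase_registry):
        tool = tool_by_name(usecase_registry, "runRPSBlast")
        op = usecase_registry.get_operations(tool.id)[0]
        with pytest.raises(BadKind):
            usecase_registry.add_parameter(op.id, "x", "inout", "Object")

    def test_usecase_parameter_declarations(self, usecase_registry):
        get_seq = tool_by_name(usecase_registry, "getAminoAcidSequence")
        descriptors = usecase_registry.generate_interface(
            get_seq.operation_ids[0]
        )
        assert [(d.name, d.kind, d.datatype) for d in descriptors] == [
            ("id", "input", "Object"),
            ("sequence", "output", "AminoAcidSequence"),
        ]

    def test_generate_interface_unknown_operation(self, usecase_registry):
        with pytest.raises(NotFound):
            usecase_registry.generate_interface("operation-none")


class TestLocations:
    def test_location_listed_under_tool(self, usecase_registry):
        tool = tool_by_name(usecase_registry, "runRPSBlast")
        locations = usecase_registry.get_locations(tool.id)
        assert len(locations) == 1
        assert locations[0].protocol == "biomoby"

    def test_mirrors_accumulate(self, usecase_registry):
        tool = tool_by_name(usecase_registry, "runRPSBlast")
        usecase_registry.new_tool_location(tool.id, "soap", "http://mirror/soap")
        assert len(usecase_registry.get_locations(tool.id)) == 2

    def test_location_for_unknown_tool(self, usecase_registry):
        with pytest.raises(UnresolvedReference):
            usecase_registry.new_tool_location("tool-missing", "local", "x")

    def test_operationless_protocol_synthesizes_virtual_operation(self):
        registry = Registry(seed=0)
        tool = registry.new_tool("bareService")
        registry.new_tool_location(tool.id, "biomoby", "http://host/moby")
        ops = registry.get_operations(tool.id)
        assert len(ops) == 1 and ops[0].virtual


class TestFilters:
    def test_substring_filter(self, usecase_registry):
        tools = usecase_registry.get_tool_list([name_contains("RPS")])
        assert [t.name for t in tools] == ["runRPSBlast"]

    def test_filter_conjunction_equals_intersection(self):
        rng = random.Random(7)
        registry = Registry(seed=7)
        add_category(registry, "A")
        add_category(registry, "B")
        for i in range(40):
            cats = [c for c in ("A", "B") if rng.random() < 0.5]
            registry.new_tool(f"tool{i}{'x' if rng.random() < 0.5 else 'y'}", categories=cats)
        f1, f2 = name_contains("x"), in_category("A")
        both = {t.id for t in registry.get_tool_list([f1, f2])}
        swapped = {t.id for t in registry.get_tool_list([f2, f1])}
        expected = {t.id for t in registry.get_tool_list([f1])} & {
            t.id for t in registry.get_tool_list([f2])
        }
        assert both == swapped == expected


class TestRetrievalAndEditing:
    def test_get_resource_roundtrip(self, usecase_registry):
        tool = tool_by_name(usecase_registry, "runRPSBlast")
        assert usecase_registry.get_resource("tool", tool.id) is tool

    def test_get_unknown_resource(self, usecase_registry):
        with pytest.raises(NotFound):
            usecase_registry.get_resource("tool", "tool-missing")

    def test_read_your_writes(self, usecase_registry):
        tool = tool_by_name(usecase_registry, "runRPSBlast")
        usecase_registry.update_resource("tool", tool.id, {"description": "new"})
        assert usecase_registry.get_resource("tool", tool.id).description == "new"

    def test_id_is_immutable(self, usecase_registry):
        tool = tool_by_name(usecase_registry, "runRPSBlast")
        with pytest.raises(ImmutableField):
            usecase_registry.update_resource("tool", tool.id, {"id": "other"})

    def test_identity_update_writes_nothing(self):
        backend = CountingBackend()
        registry = Registry(seed=0, backends={"tool": backend})
        tool = registry.new_tool("t")
        writes = backend.writes
        registry.update_resource("tool", tool.id, {})
        assert backend.writes == writes

    def test_update_unknown_id(self, usecase_registry):
        with pytest.raises(NotFound):
            usecase_registry.update_resource("tool", "tool-missing", {"name": "x"})

    def test_rename_on_reregistration_backend_preserves_references(self):
        """Editing over a register/deregister-only repository is transparent."""
        registry = Registry(seed=0, backends={"tool": ReRegistrationBackend()})
        tool = registry.new_tool("oldName")
        op = registry.add_operation(tool.id, "op")
        updated = registry.update_resource("tool", tool.id, {"name": "newName"})
        assert updated.id == tool.id and updated.name == "newName"
        assert registry.get_resource("operation", op.id).tool_ref == tool.id
        assert registry.check_integrity() == []

    def test_edit_emulation_equivalence(self):
        """Native-edit and re-registration backends end in identical stores."""

        def build(backend_cls):
            registry = Registry(
                seed=3, backends={k: backend_cls() for k in ("tool", "operation")}
            )
            add_datatype(registry, DatatypeNode("Object"))
            tool = registry.new_tool("t", "d")
            op = registry.add_operation(tool.id, "o")
            registry.add_parameter(op.id, "in", "input", "Object")
            registry.update_resource("tool", tool.id, {"name": "renamed"})
            registry.update_resource("operation", op.id, {"name": "op2"})
            return registry

        from mobykit.backends import MemoryBackend

        native = build(MemoryBackend)
        emulated = build(ReRegistrationBackend)
        assert dumps_registry(native) == dumps_registry(emulated)


class TestCascadeDeletion:
    def test_reject_while_dependencies_exist(self, usecase_registry):
        with pytest.raises(DependencyExists):
            usecase_registry.delete_resource("datatype", "GenericSequence", cascade=False)

    def test_cascade_removes_descendants_and_parameters_but_keeps_tools(
        self, usecase_registry
    ):
        report = usecase_registry.delete_resource(
            "datatype", "GenericSequence", cascade=True
        )
        assert "GenericSequence" in report.removed
        assert "AminoAcidSequence" in report.removed
        # both tools survive with their sequence parameters removed
        assert len(usecase_registry.get_tool_list()) == 2
        assert usecase_registry.check_integrity() == []
        remaining_params = [
            p.datatype_ref
            for op in usecase_registry.backend("operation").list()
            for p in op.parameters
        ]
        assert "GenericSequence" not in remaining_params
        assert "AminoAcidSequence" not in remaining_params

    def test_cascade_report_matches_dependency_closure_oracle(self, usecase_registry):
        """Report contents equal an independent full-scan dependency closure."""
        doomed = {"GenericSequence", "AminoAcidSequence"}
        expected_params = {
            p.id
            for op in usecase_registry.backend("operation").list()
            for p in op.parameters
            if p.datatype_ref in doomed
        }
        report = usecase_registry.delete_resource(
            "datatype", "GenericSequence", cascade=True
        )
        assert set(report.removed) == doomed | expected_params

    def test_delete_unreferenced_namespace(self):
        registry = Registry(seed=0)
        add_namespace(registry, "Orphan")
        report = registry.delete_resource("namespace", "Orphan", cascade=False)
        assert report.removed == ["Orphan"]

    def test_delete_unknown_resource(self, usecase_registry):
        with pytest.raises(NotFound):
            usecase_registry.delete_resource("datatype", "Nope", cascade=True)

    def test_category_cascade_strips_annotations(self, usecase_registry):
        report = usecase_registry.delete_resource("category", "Alignment", cascade=True)
        assert report.removed == ["Alignment"]
        tool = tool_by_name(usecase_registry, "runRPSBlast")
        assert tool.category_refs == []
        assert usecase_registry.check_integrity() == []

    def test_referential_integrity_after_random_edits(self):
        """No dangling references after any add/update/delete(cascade) mix."""
        rng = random.Random(11)
        registry = build_usecase_registry(seed=5)
        for step in range(60):
            roll = rng.random()
            tools = registry.get_tool_list()
            if roll < 0.3:
                registry.new_tool(f"t{step}")
            elif roll < 0.5 and tools:
                tool = rng.choice(tools)
                registry.add_operation(tool.id, f"op{step}")
            elif roll < 0.7 and tools:
                tool = rng.choice(tools)
                ops = registry.get_operations(tool.id)
                if ops:
                    registry.add_parameter(
                        rng.choice(ops).id, f"p{step}", "input", "Object"
                    )
            elif roll < 0.85 and tools:
                registry.delete_resource("tool", rng.choice(tools).id, cascade=True)
            else:
                names = [n.name for n in registry.backend("datatype").list()]
                if len(names) > 1:
                    victim = rng.choice([n for n in names if n != "Object"])
                    registry.delete_resource("datatype", victim, cascade=True)
            assert registry.check_integrity() == []


class TestLayers:
    def test_cache_serves_second_read_without_backend_call(self):
        backend = CountingBackend()
        registry = Registry(seed=0, backends={"tool": backend})
        tool = registry.new_tool("cached")
        registry.attach_layer("tool", "cache")
        registry.get_resource("tool", tool.id)
        reads = backend.reads
        registry.get_resource("tool", tool.id)
        assert backend.reads == reads

    def test_write_invalidates_cache(self):
        backend = CountingBackend()
        registry = Registry(seed=0, backends={"tool": backend})
        tool = registry.new_tool("stale")
        registry.attach_layer("tool", "cache")
        registry.get_resource("tool", tool.id)
        registry.update_resource("tool", tool.id, {"name": "fresh"})
        assert registry.get_resource("tool", tool.id).name == "fresh"

    def test_unknown_layer(self, usecase_registry):
        with pytest.raises(UnknownLayer):
            usecase_registry.attach_layer("tool", "turbo")

    def test_layer_transparency_on_random_call_sequence(self):
        """Cached and uncached modules answer every call identically."""

        def run(with_cache: bool):
            registry = build_usecase_registry(seed=9)
            if with_cache:
                for kind in ("tool", "operation", "datatype"):
                    registry.attach_layer(kind, "cache")
            rng = random.Random(13)
            trace = []
            for step in range(40):
                tools = registry.get_tool_list()
                trace.append([t.name for t in tools])
                roll = rng.random()
                if roll < 0.3:
                    trace.append(registry.new_tool(f"t{step}").name)
                elif roll < 0.6 and tools:
                    tool = rng.choice(tools)
                    registry.update_resource("tool", tool.id, {"description": str(step)})
                    trace.append(registry.get_resource("tool", tool.id).description)
                elif tools:
                    tool = rng.choice(tools)
                    trace.append(
                        [d.name for d in registry.generate_interface(op_id)]
                        if (op_id := (tool.operation_ids or [None])[0])
                        else None
                    )
            return trace

        assert run(True) == run(False)
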