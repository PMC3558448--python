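"""Fixture registries: the worked-example registry and a synthetic generator.

The worked example models a homologous-protein-finder setting: a provider
deploys two BioMOBY services — ``getAminoAcidSequence`` (database retrieval
by identifier) and ``runRPSBlast`` (profile search producing a textual BLAST
report) — against the BioMOBY base taxonomy (Object, VirtualSequence,
GenericSequence, AminoAcidSequence, BLAST-Text).  The composition engine can
chain them because AminoAcidSequence IS-A GenericSequence.

The synthetic generator produces seeded random registries (acyclic taxonomy,
resolvable references, optional planted type-compatible chains) for property
tests; the same seed yields a byte-identical store.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .data_engine import DataEngine, StructuredData
from .errors import BadSpec
from .execution import ExecutionEngine, MockBiomobyWorker
from .records import DatatypeNode
from .registry import Registry
from .taxonomy import add_category, add_datatype, add_namespace

#: Canned protein returned by the mock retrieval service.
CANNED_PROTEIN = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"


def build_usecase_registry(seed: int | None = 0) -> Registry:
    """The worked-example registry: BioMOBY base taxonomy plus two services."""
    registry = Registry(seed=seed)

    add_datatype(registry, DatatypeNode("Object", "root of the BioMOBY taxonomy"))
    add_datatype(
        registry,
        DatatypeNode(
            "VirtualSequence",
            "a sequence without the sequence characters",
            is_parent="Object",
            attributes=[("id", "String"), ("namespace", "String"), ("length", "Integer")],
        ),
    )
    add_datatype(
        registry,
        DatatypeNode(
            "GenericSequence",
            "a sequence carrying its characters",
            is_parent="VirtualSequence",
            attributes=[("SequenceString", "String")],
        ),
    )
    add_datatype(
        registry,
        DatatypeNode(
            "AminoAcidSequence", "a protein sequence", is_parent="GenericSequence"
        ),
    )
    add_datatype(
        registry,
        DatatypeNode(
            "BLAST-Text",
            "textual BLAST report",
            is_parent="Object",
            attributes=[("content", "String")],
        ),
    )

    add_category(registry, "Retrieval", "fetch records from databases")
    add_category(registry, "Alignment", "sequence comparison and search")
    add_namespace(registry, "UniProt", "protein knowledgebase accessions")

    get_seq = registry.new_tool(
        "getAminoAcidSequence",
        "retrieve a protein sequence by identifier",
        categories=["Retrieval"],
    )
    op1 = registry.add_operation(get_seq.id, "getAminoAcidSequence")
    registry.add_parameter(op1.id, "id", "input", "Object", namespace="UniProt")
    registry.add_parameter(op1.id, "sequence", "output", "AminoAcidSequence")
    registry.new_tool_location(
        get_seq.id, "biomoby", "http://services.example.org/moby/getAminoAcidSequence"
    )

    rps = registry.new_tool(
        "runRPSBlast",
        "search a sequence against conserved-domain profiles",
        categories=["Alignment"],
    )
    op2 = registry.add_operation(rps.id, "runRPSBlast")
    registry.add_parameter(op2.id, "sequence", "input", "GenericSequence")
    registry.add_parameter(op2.id, "blast_report", "output", "BLAST-Text")
    registry.new_tool_location(
        rps.id, "biomoby", "http://services.example.org/moby/runRPSBlast"
    )
    return registry


def build_usecase_workers(engine: DataEngine) -> MockBiomobyWorker:
    """Mock BioMOBY worker with canned handlers for the two example services."""

    def get_amino_acid_sequence(operation, inputs):
        query = engine.parse(inputs["id"], "moby-xml", "Object")
        data = StructuredData(
            "AminoAcidSequence",
            attributes={
                "id": query.attributes.get("id", "") or "P0A7B8",
                "namespace": "UniProt",
                "SequenceString": CANNED_PROTEIN,
            },
        )
        loaded, _ = engine.apply_loaders(data)
        return {"sequence": engine.serialize(loaded, "moby-xml")}

    def run_rps_blast(operation, inputs):
        sequence = engine.parse(inputs["sequence"], "moby-xml", "GenericSequence")
        seq = sequence.attributes.get("SequenceString", "")
        report = (
            f"RPS-BLAST 2.2.x\nQuery= {sequence.attributes.get('id', '')}"
            f" ({len(seq)} letters)\n\nSignificant alignments:\ncd00000"
            "  example conserved domain   42.0   1e-05\n"
        )
        data = StructuredData(
            "BLAST-Text", attributes={"id": "", "namespace": "", "content": report}
        )
        loaded, _ = engine.apply_loaders(data)
        return {"blast_report": engine.serialize(loaded, "moby-xml")}

    return MockBiomobyWorker(
        {
            "getAminoAcidSequence": get_amino_acid_sequence,
            "runRPSBlast": run_rps_blast,
        }
    )


def build_usecase_execution(
    seed: int | None = 0,
) -> tuple[Registry, DataEngine, ExecutionEngine]:
    """Registry + data engine + execution engine with the mock worker wired."""
    registry = build_usecase_registry(seed=seed)
    engine = DataEngine(registry)
    execution = ExecutionEngine(registry, engine)
    execution.register_worker(build_usecase_workers(engine))
    return registry, engine, execution


@dataclass
class FixtureSpec:
    """Shape of a synthetic random registry (deterministic per seed)."""

    seed: int = 0
    n_datatypes: int = 12
    taxonomy_depth: int = 4
    n_tools: int = 6
    ops_per_tool: tuple[int, int] = (1, 1)
    inputs_per_op: tuple[int, int] = (1, 2)
    outputs_per_op: tuple[int, int] = (1, 1)
    chain_fraction: float = 0.5

    def validate(self) -> None:
        if self.n_datatypes < 1:
            raise BadSpec("need at least one datatype (the root)")
        if self.n_tools < 0 or self.taxonomy_depth < 1:
            raise BadSpec("negative tool count or non-positive depth")
        for lo, hi in (self.ops_per_tool, self.inputs_per_op, self.outputs_per_op):
            if lo < 1 or hi < lo:
                raise BadSpec("ranges must be 1 <= lo <= hi")
        if not 0.0 <= self.chain_fraction <= 1.0:
            raise BadSpec("chain_fraction must be within [0, 1]")


def generate_random_taxonomy(
    registry: Registry, rng: random.Random, n_nodes: int, max_depth: int = 5
) -> list[str]:
    """Populate a registry with a random acyclic datatype forest; returns names."""
    names: list[str] = []
    depths: dict[str, int] = {}
    for i in range(n_nodes):
        name = f"DT{i:03d}"
        parent = None
        if names and rng.random() < 0.8:
            candidates = [n for n in names if depths[n] < max_depth - 1]
            if candidates:
                parent = rng.choice(candidates)
        attributes = []
        if rng.random() < 0.5:
            attributes.append((f"attr_{name}", rng.choice(["String", "Integer"])))
        add_datatype(
            registry,
            DatatypeNode(name, is_parent=parent, attributes=attributes),
        )
        depths[name] = 0 if parent is None else depths[parent] + 1
        names.append(name)
    return names


def generate_synthetic_registry(spec: FixtureSpec) -> Registry:
    """A deterministic random registry; plants a findable source->target chain
    with probability ``chain_fraction`` (guaranteed when the fraction is 1.0,
    and at least one chain overall whenever the fraction is positive).

    When a chain is planted, datatypes ``ChainSource`` and ``ChainTarget``
    exist and a type-compatible path connects them.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    registry = Registry(seed=spec.seed)
    names = generate_random_taxonomy(
        registry, rng, spec.n_datatypes, spec.taxonomy_depth
    )
    add_category(registry, "Generated", "synthetic fixture tools")

    def random_params(op_id: str) -> None:
        n_in = rng.randint(*spec.inputs_per_op)
        n_out = rng.randint(*spec.outputs_per_op)
        for j in range(n_in):
            registry.add_parameter(op_id, f"in{j}", "input", rng.choice(names))
        for j in range(n_out):
            registry.add_parameter(op_id, f"out{j}", "output", rng.choice(names))

    for t in range(spec.n_tools):
        tool = registry.new_tool(f"tool{t:02d}", "synthetic", categories=["Generated"])
        for o in range(rng.randint(*spec.ops_per_tool)):
            operation = registry.add_operation(tool.id, f"op{o}")
            random_params(operation.id)
        registry.new_tool_location(tool.id, "local", f"local://tool{t:02d}")

    plant = spec.chain_fraction > 0 and (
        spec.chain_fraction >= 1.0 or rng.random() < spec.chain_fraction
    )
    if plant:
        add_datatype(registry, DatatypeNode("ChainSource"))
        add_datatype(registry, DatatypeNode("ChainTarget"))
        chain = ["ChainSource"]
        for _ in range(rng.randint(0, 2)):
            if names and rng.random() < 0.5:
                chain.append(rng.choice(names))
        chain.append("ChainTarget")
        for k in range(len(chain) - 1):
            tool = registry.new_tool(f"chain{k:02d}", "planted", categories=["Generated"])
            operation = registry.add_operation(tool.id, "link")
            registry.add_parameter(operation.id, "in0", "input", chain[k])
            registry.add_parameter(operation.id, "out0", "output", chain[k + 1])
            registry.new_tool_location(tool.id, "local", f"local://chain{k:02d}")
    return registry
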