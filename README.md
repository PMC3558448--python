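# mobykit

A software framework for building clients that integrate heterogeneous
bioinformatics web services. Combining such services into pipelines is hard
because they differ in access protocol (BioMOBY, SOAP, local tools, ...) and
in data format (FASTA, GenBank, raw sequence text, XML dialects). `mobykit`
gives client code one uniform model of service metadata, discovers
type-compatible service chains automatically, converts user data between
formats through a structured intermediate representation, and runs the
chains through pluggable protocol workers — all offline-testable, with mock
workers standing in for live endpoints.

## The model

**Metadata registry.** An abstract *tool* groups *operations*; each
operation declares typed *parameters* (`input` / `output` / `secondary`);
concrete deployments are *tool locations* (endpoint mirrors, possibly over
different protocols). Tools are annotated with hierarchical *functional
categories*, and *namespaces* label data provenance. Every module is split
into an *Access* layer (a pluggable backend mapping a concrete repository
into the common records) and an *Interface* layer (the uniform API);
additional layers such as a read cache stack between them without changing
the Interface. Repositories whose API cannot edit in place (register /
deregister only) still support editing — the Interface layer emulates an
update as a single deregister+register transaction that preserves the id.

**Datatype taxonomy.** Datatypes form a BioMOBY-style object-oriented
taxonomy: single-inheritance IS edges, primitive attributes, HAS parts
(arrays) and HASA parts (single sub-objects). A service declaring an input
of datatype `D` accepts any instance of `D` or an IS-descendant:

&nbsp;&nbsp;&nbsp;&nbsp;`accepts(op, x)  ⇔  ∃ input parameter p of op : x.datatype ⊑ p.datatype`

where `⊑` is the reflexive-transitive closure of IS. The shipped base
taxonomy has `GenericSequence ⊑ VirtualSequence ⊑ Object`, with
`VirtualSequence` carrying `id`, `namespace`, `length` and
`GenericSequence` adding `SequenceString`.

**Composition.** Every (operation, input, output) triple is a directed edge
from the acceptance set of its input datatype to its output datatype. A
*pipeline* from source `S` to target `T` is an edge sequence
`e₁ … eₖ` with `S ⊑ in(e₁)`, `out(eᵢ) ⊑ in(eᵢ₊₁)` and `out(eₖ) ⊑ T`.
`find_path` returns a shortest pipeline (breadth-first search with a
deterministic lexicographic tie-break); `enumerate_paths` lists all
pipelines up to a depth bound.

**Data engine.** User data is parsed into a typed tree (`StructuredData`).
*Loaders* are transforms scoped to a datatype and all its descendants,
applied seamlessly ancestor-first — e.g. converting raw sequence text to
the BioMOBY XML dialect runs exactly two: the base loader injecting the
mandatory `id`/`namespace` attributes and the length loader computing
`length = |SequenceString|`. *Formatters* serialize/parse wire formats
(FASTA, raw, GenBank read-only, a documented `moby-xml` dialect), and
regular-expression heuristics recognize the format and alphabet of raw user
input.

**Execution.** Protocol *workers* invoke endpoints; tasks follow a strict
`SUBMITTED → RUNNING → SUCCEEDED | FAILED` machine with an audited event
log, mirrors are selected round-robin with optional failover, and every
invocation feeds per-endpoint usage statistics.

## Worked example

The bundled worked example models a homologous-protein search: a provider
registers `getAminoAcidSequence` (input `id: Object`, output
`sequence: AminoAcidSequence`) and `runRPSBlast` (input
`sequence: GenericSequence`, output `blast_report: BLAST-Text`).

```sh
mobykit register --registry reg.json --usecase
# {"tools": 2}
mobykit compose --from Object --to BLAST-Text --registry reg.json
```

prints a 2-stage pipeline (`"length": 2`): `getAminoAcidSequence` then
`runRPSBlast`, linked through `AminoAcidSequence` — the services connect
even though the declared datatypes differ, because
`AminoAcidSequence ⊑ GenericSequence`.

```sh
printf 'MKTAYIAK' > seq.raw
mobykit convert seq.raw --to moby-xml --as GenericSequence --registry reg.json
```

```xml
<GenericSequence id="" namespace=""><Integer articleName="Length">8</Integer><String articleName="SequenceString">MKTAYIAK</String></GenericSequence>
```

The raw eight-residue sequence was recognized (`mobykit detect seq.raw` →
`raw protein`), structured as a `GenericSequence`, and the two BioMOBY
loaders ran seamlessly: `Length` is 8 and the mandatory `id`/`namespace`
attributes exist. Enacting the discovered pipeline with the built-in mock
workers:

```sh
printf '>P0A7B8\nMKTAYIAK\n' > query.fasta
mobykit run --from Object --to BLAST-Text --input query.fasta \
        --registry reg.json --as GenericSequence
```

logs two `SUCCEEDED` tasks and prints the final `BLAST-Text` document;
`mobykit stats --registry reg.json` then shows one invocation (one success)
per endpoint.

The same flows are available as a library:

```python
from mobykit import build_usecase_execution, find_path, StructuredData

registry, engine, execution = build_usecase_execution()
pipeline = find_path(registry, "Object", "BLAST-Text")      # 2 stages
outcome = execution.enact_pipeline(
    pipeline, StructuredData("Object", {"id": "P0A7B8", "namespace": "UniProt"})
)
print(outcome.data.datatype)                                 # BLAST-Text
```

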