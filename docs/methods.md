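# Methods

This note documents the models and procedures `mobykit` implements, the
design choices made where the design was genuinely open, the numerical and
tie-breaking conventions, what the synthetic fixtures emulate, and the known
limitations.

## Module framework: Access / Interface layering

Every module (datatype, category, namespace, tool, operation, location) is
served by a backend implementing a small contract: `list`, `get`, `add`,
`delete`, `register`/`deregister`, and — only where the underlying
repository supports it (`native_edit`) — `update`. The `Registry` class is
the Interface layer: it owns one backend per module, enforces referential
preconditions, and routes edits. On a backend without native editing,
`update_resource` is emulated as deregister + register preserving the id.
For the in-process backends the two steps form one transaction (the old
record is restored if re-registration fails), eliminating the transient
inconsistency window that remote register/deregister repositories exhibit;
the contract documents that remote accesses may not be atomic. A test
asserts that the two editing routes leave byte-identical stores.

Extra layers follow the same backend contract and stack between Interface
and Access. The shipped `cache` layer serves repeated reads without a
backend call and invalidates on every write; a differential test replays a
random call sequence against cached and uncached modules and requires
identical answers.

**Identity.** Ids are opaque strings. With a configured seed they are
deterministic (`kind-NNNN-<sha1 prefix>` over seed, kind and a per-kind
counter) so fixtures are byte-reproducible; without a seed they are random
UUIDs. Names are the identity only for taxonomy nodes, categories and
namespaces. Tool names are not forced unique by default (identity is the
id); a registry flag enables uniqueness for repositories that need it.

**Cascade graph.** Deletion dependents are: datatype → its IS-descendants
and every parameter referencing the doomed set (parts referencing it are
stripped in place and reported separately); category → child categories,
with tool annotations stripped (tools survive); namespace → referencing
parameters; tool → its operations (with their parameters) and locations.
`cascade=False` rejects while any dependent exists. Operations themselves
delete their nested parameters and strip the tool's reference — nothing
outside the tool depends on an operation. After any edit sequence a
full-scan referential-integrity check must come back empty; this is a
standing property test.

## Datatype taxonomy and subtyping

Nodes have a single IS parent (the IS graph must be a forest), primitive
attributes (`String`, `Integer`, `Float`, `Boolean`), HAS parts
(cardinality many) and HASA parts (cardinality one). Effective structure is
own ∪ inherited, materialized ancestor-first. Choices made where the model
was open:

* **Single inheritance.** Multiple IS parents are not representable;
  `reparent` re-checks acyclicity and rejects moves under a descendant.
* **Shadowing is an error.** A child redeclaring an inherited attribute
  name would make the effective set ambiguous; `add_datatype` rejects it
  and `validate_taxonomy` reports it.
* **Substitutability uses IS only.** HAS/HASA express containment, never
  subtype compatibility.
* **Primitives are a closed enum**, not taxonomy nodes; they appear as
  element names in the XML dialect below.
* **Universal attributes.** `id` and `namespace` are permitted on any
  structured instance regardless of the declared attribute set, because the
  BioMOBY contract puts them on every object while the shipped taxonomy
  declares them (with `length`) on `VirtualSequence`.

`is_subtype_of` is reflexive and transitive by construction and
antisymmetric on any validated taxonomy; tests compare it against an
independently computed transitive closure on seeded random taxonomies.

## Pipeline composition

The search space treats datatypes as nodes and (operation, input parameter,
output parameter) triples as edges; an edge accepts every subtype of its
declared input. Secondary parameters never participate. `find_path` is a
level-synchronous BFS: within a level, candidate chains are generated in
lexicographic (tool name, operation name) order and only the first chain
reaching a datatype survives — because continuations depend only on the
datatype reached, the lexicographically smallest shortest path always
extends such a prefix, making the tie-break exact. "Optimum" means fewest
operations; no cost model beyond hop count is implemented. The depth bound
defaults to 6 operations.

Multi-input operations do not block composition: the chain feeds exactly
one input and the remaining mandatory inputs are reported as
`unresolved_inputs` for the client to collect (enactment requires them as
`extra_inputs`). `enumerate_paths` performs depth-bounded exhaustive
enumeration (including the empty pipeline when the source already satisfies
the target) sorted by length then name sequence, and `validate_pipeline`
re-checks every link independently of the search. Note that an input typed
at the taxonomy root accepts *everything*; registries containing such
operations admit looped pipelines at higher depth bounds, which
`enumerate_paths` faithfully reports.

## Structured data, loaders, formatters

`StructuredData` is a typed tree: attribute map, part map (lists for HAS
parts), an optional provenance tag naming the source format. `get_part` /
`set_part` navigate `/`-separated paths, validate that each segment is
declared, return a `MISSING` sentinel for declared-but-unset values, and
type-check writes against the declared primitive (Booleans are not
Integers).

**Loaders** apply to a scope datatype and all IS-descendants, each exactly
once, ordered ancestor-first, then by priority, then registration order —
so the base loader (scoped at `Object`: inject empty-string `id` and
`namespace` when absent) always precedes the length loader (scoped at
`GenericSequence`: recompute `length = |SequenceString|`). Both shipped
loaders are idempotent; the empty-string default for absent identifiers is
a deliberate choice (failing on absent ids would make raw-data conversion
impossible). The length loader is scoped at `GenericSequence` rather than
`VirtualSequence` (where `length` is declared) because the transform needs
`SequenceString` to exist. Loaders can be disabled by name through the
persisted configuration. Data is fully loaded in memory; on-demand partial
loading is left as a contract note for alternative loader implementations.

**Formatters** cover a scope datatype and its descendants:

| format     | parse | serialize | lossy | notes |
|------------|-------|-----------|-------|-------|
| `fasta`    | yes   | yes       | no    | canonical output: one header line (`>` + id), sequence unwrapped; multi-record input keeps the first record |
| `raw`      | yes   | yes       | no    | sequence characters only |
| `genbank`  | yes   | no        | yes   | Biopython flat-file parser; accession + sequence extracted, everything else discarded with a `LossyFormatWarning` — the conversion cannot be reversed |
| `moby-xml` | yes   | yes       | no    | dialect below |
| `fastq`    | —     | —         | —     | detection only |

**moby-xml dialect** (defined here; locked by golden-file tests): the
element is named after the datatype; `id` and `namespace` are XML
attributes; every other attribute becomes a child element named after its
primitive with `articleName` set to the attribute name
first-letter-uppercased (`length` → `Length`); parts become nested datatype
elements carrying `articleName`; children are sorted by `articleName` for
deterministic bytes. Parsing inverts the capitalization by matching against
the declared effective attributes. Example:

```xml
<GenericSequence id="s1" namespace=""><Integer articleName="Length">3</Integer><String articleName="SequenceString">MKT</String></GenericSequence>
```

`parse ∘ serialize` is the identity on `StructuredData` for the non-lossy
formats over their respective images (for `moby-xml`, loader-normalized
data — i.e. `id`/`namespace` present, as the standard requires).

**Format detection** is an ordered rule table (priority ascending): GenBank
(`LOCUS` header), FASTQ (`@` + `+` separator), XML, FASTA (`>` header), raw
(letters/gaps only); first match wins, unknown otherwise. The alphabet
heuristic calls a sequence nucleotide when ≥ 90% of its letters are in
`ACGTUN`, protein otherwise — a simple fraction rule adequate for routing,
not a rigorous classifier. All thresholds and priorities are package
choices, and new rules/heuristics can be registered.

`convert` chains detect → parse → apply loaders → serialize and annotates
any failure with the stage that raised.

## Execution

Workers are protocol plug-ins registered per protocol tag. A worker that
declares a wire format makes the engine adapt data around the call: inputs
pass through the in-scope loaders and are serialized; outputs matching
declared output parameters are parsed back into typed trees. A worker with
no wire format exchanges structured data directly (the local echo worker).
Workers run synchronously in-process; the submit / poll / retrieve
lifecycle of remote reference-passing deployments is modeled by the same
three calls (`add_task`, `get_status`, `get_results`) without a real
network hop, and inputs may be opaque references a worker resolves itself.

Tasks enforce `SUBMITTED → RUNNING → {SUCCEEDED, FAILED}`; every transition
is appended to an event log and `audit_task` independently replays the log.
Results are unavailable before `SUCCEEDED` (`NotFinished` carries the error
payload of failed tasks). Statistics (invocations, successes, cumulative
latency per location) live in the registry and persist in the store across
sessions. Endpoint selection is round-robin over locations with a
registered worker; `invoke_operation` optionally retries a failed
invocation once on the next mirror (on by default, configurable).
Scheduling beyond round-robin is out of scope.

The mock BioMOBY worker is synthetic: it answers in `moby-xml` from canned
handlers (a fixed protein for retrieval, a templated report for the profile
search), standing in for live endpoints, which the package does not call.

## Fixtures and what the tests do (and do not) show

The worked-example registry (five datatypes, two tools, two categories, one
namespace, one BioMOBY location each) is built by seeded API calls, so the
store is byte-reproducible. The synthetic generator emulates registry
*shape* — an acyclic random taxonomy (80% of nodes get a parent, depth
capped), tools with 1–2 typed inputs and one output, locations, and
optionally a planted compatible chain between `ChainSource` and
`ChainTarget` — with all references valid by construction. It does not
emulate real-world metadata quality: no dangling references, no contested
names, no skewed taxonomy shapes, no live protocol behavior. Passing tests
therefore demonstrate the algebraic contracts (subtype algebra, search
minimality, round-trips, lifecycle legality) rather than robustness against
arbitrary third-party repositories.

Problem sizes used by the acceptance checks — 200 taxonomies of 10–50
nodes, 100 registries of ≤ 8 single-operation tools with oracle enumeration
depth 4, 1,000 random sequences of length 1–120, 500 task runs with 25%
injected failures — were chosen as the smallest scales at which the
brute-force oracles still exercise non-trivial structure; all complete in
seconds.

## Known limitations

* No live network bindings (BioMOBY/SOAP/Taverna); the worker contract plus
  mocks replace them. No users/permissions module, no file-system module,
  no reasoner, no statistics-driven scheduling.
* GenBank support is read-only and partial (accession + sequence); writing
  GenBank is not implemented, so GenBank round-trips are impossible by
  design, not just lossy.
* The store is a single JSON document per repository; very large registries
  would need a paged backend behind the same contract.
* Root-typed inputs make everything reachable from everything in
  composition; clients that want stricter discovery should avoid annotating
  service inputs at the taxonomy root.
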