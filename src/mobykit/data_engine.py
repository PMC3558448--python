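"""Structured data, loaders, formatters and format recognition.

User data is held as a DOM-like tree (:class:`StructuredData`) typed against
the shared datatype taxonomy.  Two kinds of inheritance-scoped plug-ins act
on it:

* **Loaders** transform the tree in place to satisfy a data standard — e.g.
  the BioMOBY base loader injects the mandatory ``id``/``namespace``
  attributes on every object, and the sequence-length loader computes the
  explicit ``length`` that sequence objects must carry but formats like
  FASTA do not record.  A loader scoped at datatype *D* applies to *D* and
  every IS-descendant, seamlessly (clients never name loaders).
* **Formatters** parse wire formats into trees and serialize trees back.
  Shipped dialects: FASTA (canonical single-header, unwrapped sequence),
  raw sequence text, GenBank flat file (parse-only, lossy) and a compact
  BioMOBY-style XML dialect (``moby-xml``, documented in the methods note).

Format recognition is an ordered rule set of regular-expression heuristics;
the first matching rule wins, and a simple alphabet heuristic (fraction of
letters in ``ACGTUN``) classifies sequences as nucleotide or protein.

``id`` and ``namespace`` are universal attributes: the BioMOBY contract
requires them on every object, so they are permitted on any tree regardless
of the declared attribute set.
"""

from __future__ import annotations

import copy
import io
import re
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable

from lxml import etree

from .errors import (
    ConversionError,
    DuplicateName,
    EmptyInput,
    LoaderFailure,
    LossyFormatWarning,
    MissingAttribute,
    MobyKitError,
    NoFormatter,
    BadPath,
    ParseError,
    TypeMismatch,
    UnresolvedReference,
)
from .registry import Registry
from .taxonomy import ancestors_or_self, get_datatype

#: Attributes every BioMOBY-style object may carry, declared or not.
UNIVERSAL_ATTRIBUTES = {"id": "String", "namespace": "String"}

PRIMITIVE_PYTHON = {"String": str, "Integer": int, "Float": float, "Boolean": bool}

#: Sentinel returned by get_part for declared-but-absent values.
MISSING = object()

NUCLEOTIDE_LETTERS = set("ACGTUN")
NUCLEOTIDE_FRACTION = 0.9


@dataclass
class StructuredData:
    """A typed, navigable tree instance of a taxonomy datatype."""

    datatype: str
    attributes: dict[str, Any] = field(default_factory=dict)
    parts: dict[str, Any] = field(default_factory=dict)  # StructuredData or list
    provenance: str | None = None

    def copy(self) -> "StructuredData":
        return copy.deepcopy(self)


@dataclass
class LoaderSpec:
    """A deterministic structure transformer scoped to a datatype subtree."""

    name: str
    scope_datatype: str
    transform: Callable[["DataEngine", StructuredData], StructuredData]
    priority: int = 0


@dataclass
class FormatterSpec:
    """A parser/serializer pair between trees and one wire format."""

    format_id: str
    scope_datatype: str
    parse: Callable[["DataEngine", bytes, str], StructuredData] | None = None
    serialize: Callable[["DataEngine", StructuredData], bytes] | None = None
    lossy: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            self.name = f"{self.format_id}:{self.scope_datatype}"


@dataclass
class FormatRule:
    """One detection heuristic; lower priority value is evaluated first."""

    format_id: str
    priority: int
    matches: Callable[[bytes], bool]
    sequence_region: Callable[[bytes], str | None] = lambda content: None


@dataclass
class ConversionResult:
    content: bytes
    source_format: str
    alphabet: str
    applied_loaders: list[str]
    data: StructuredData


def classify_alphabet(sequence: str | None) -> str:
    if not sequence:
        return "n/a"
    letters = [c.upper() for c in sequence if c.isalpha()]
    if not letters:
        return "n/a"
    fraction = sum(c in NUCLEOTIDE_LETTERS for c in letters) / len(letters)
    return "nucleotide" if fraction >= NUCLEOTIDE_FRACTION else "protein"


# ---- shipped detection rules --------------------------------------------------

def _text(content: bytes) -> str:
    return content.decode("utf-8", errors="replace")


def _fasta_sequence(content: bytes) -> str | None:
    lines = _text(content).splitlines()
    return "".join(l.strip() for l in lines[1:] if not l.startswith(">"))


def _genbank_sequence(content: bytes) -> str | None:
    text = _text(content)
    m = re.search(r"^ORIGIN.*?$(.*?)^//", text, re.MULTILINE | re.DOTALL)
    if not m:
        return None
    return "".join(c for c in m.group(1) if c.isalpha())


def _fastq_sequence(content: bytes) -> str | None:
    lines = _text(content).splitlines()
    return lines[1].strip() if len(lines) > 1 else None


def _raw_sequence(content: bytes) -> str | None:
    return "".join(_text(content).split())


def _is_moby_xml(content: bytes) -> bool:
    if not content.lstrip().startswith(b"<"):
        return False
    try:
        etree.fromstring(content)
        return True
    except etree.XMLSyntaxError:
        return False


DEFAULT_RULES: list[FormatRule] = [
    FormatRule(
        "genbank", 10,
        lambda c: re.match(rb"^LOCUS\s", c) is not None,
        _genbank_sequence,
    ),
    FormatRule(
        "fastq", 20,
        lambda c: (
            c.startswith(b"@")
            and len(c.splitlines()) >= 4
            and c.splitlines()[2].startswith(b"+")
        ),
        _fastq_sequence,
    ),
    FormatRule("moby-xml", 30, _is_moby_xml),
    FormatRule("fasta", 40, lambda c: c.lstrip().startswith(b">"), _fasta_sequence),
    FormatRule(
        "raw", 50,
        lambda c: re.fullmatch(rb"[A-Za-z*\-\s]+", c) is not None,
        _raw_sequence,
    ),
]


# ---- shipped loaders -----------------------------------------------------------

def _moby_base_transform(engine: "DataEngine", data: StructuredData) -> StructuredData:
    """Every BioMOBY object must carry an identifier and a namespace."""
    data.attributes.setdefault("id", "")
    data.attributes.setdefault("namespace", "")
    return data


def _sequence_length_transform(
    engine: "DataEngine", data: StructuredData
) -> StructuredData:
    """Sequence objects carry their length explicitly; recompute it from the
    sequence characters so the loader is idempotent."""
    sequence = data.attributes.get("SequenceString")
    if sequence is not None:
        data.attributes["length"] = len(sequence)
    return data


# ---- shipped formatters ---------------------------------------------------------

def _parse_fasta(engine: "DataEngine", content: bytes, target: str) -> StructuredData:
    text = _text(content)
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines or not lines[0].startswith(">"):
        raise ParseError("FASTA content must start with a '>' header line")
    header = lines[0][1:].strip()
    identifier = header.split()[0] if header else ""
    sequence_lines = []
    for line in lines[1:]:
        if line.startswith(">"):
            break  # single-sequence model: first record only
        sequence_lines.append(line.strip())
    return StructuredData(
        datatype=target,
        attributes={"id": identifier, "SequenceString": "".join(sequence_lines)},
    )


def _serialize_fasta(engine: "DataEngine", data: StructuredData) -> bytes:
    sequence = data.attributes.get("SequenceString")
    if sequence is None:
        raise MissingAttribute("FASTA serialization requires SequenceString")
    identifier = data.attributes.get("id", "")
    return f">{identifier}\n{sequence}\n".encode()


def _parse_raw(engine: "DataEngine", content: bytes, target: str) -> StructuredData:
    sequence = "".join(_text(content).split())
    if not sequence:
        raise ParseError("raw sequence content is empty")
    return StructuredData(datatype=target, attributes={"SequenceString": sequence})


def _serialize_raw(engine: "DataEngine", data: StructuredData) -> bytes:
    sequence = data.attributes.get("SequenceString")
    if sequence is None:
        raise MissingAttribute("raw serialization requires SequenceString")
    return f"{sequence}\n".encode()


def _parse_genbank(engine: "DataEngine", content: bytes, target: str) -> StructuredData:
    from Bio import SeqIO

    try:
        record = SeqIO.read(io.StringIO(_text(content)), "genbank")
    except Exception as exc:
        raise ParseError(f"not a parseable GenBank record: {exc}") from exc
    data = StructuredData(
        datatype=target,
        attributes={"id": record.id, "SequenceString": str(record.seq).upper()},
    )
    return data


def _article_name(name: str) -> str:
    return name[0].upper() + name[1:] if name else name


def _format_primitive(primitive: str, value: Any) -> str:
    if primitive == "Boolean":
        return "true" if value else "false"
    return str(value)


def _read_primitive(primitive: str, text: str | None):
    text = text or ""
    if primitive == "Integer":
        return int(text)
    if primitive == "Float":
        return float(text)
    if primitive == "Boolean":
        return text.strip().lower() == "true"
    return text


def _infer_primitive(value: Any) -> str:
    if isinstance(value, bool):
        return "Boolean"
    if isinstance(value, int):
        return "Integer"
    if isinstance(value, float):
        return "Float"
    return "String"


def _moby_element(engine: "DataEngine", data: StructuredData) -> etree._Element:
    element = etree.Element(data.datatype)
    element.set("id", str(data.attributes.get("id", "")))
    element.set("namespace", str(data.attributes.get("namespace", "")))
    view = get_datatype(engine.registry, data.datatype)
    declared = dict(view.effective_attributes)
    children: list[tuple[str, etree._Element]] = []
    for name, value in data.attributes.items():
        if name in ("id", "namespace"):
            continue
        primitive = declared.get(name) or _infer_primitive(value)
        child = etree.Element(primitive)
        article = _article_name(name)
        child.set("articleName", article)
        child.text = _format_primitive(primitive, value)
        children.append((article, child))
    for part_name, value in data.parts.items():
        article = _article_name(part_name)
        for sub in value if isinstance(value, list) else [value]:
            child = _moby_element(engine, sub)
            child.set("articleName", article)
            children.append((article, child))
    for _, child in sorted(children, key=lambda pair: pair[0]):
        element.append(child)
    return element


def _serialize_moby(engine: "DataEngine", data: StructuredData) -> bytes:
    return etree.tostring(_moby_element(engine, data))


def _dearticle(article: str, names: list[str]) -> str:
    for name in names:
        if name == article or _article_name(name) == article:
            return name
    return article[0].lower() + article[1:] if article else article


def _moby_from_element(engine: "DataEngine", element: etree._Element) -> StructuredData:
    datatype = element.tag
    try:
        view = get_datatype(engine.registry, datatype)
    except MobyKitError as exc:
        raise ParseError(f"unknown datatype element {datatype!r}") from exc
    data = StructuredData(datatype=datatype)
    data.attributes["id"] = element.get("id", "")
    data.attributes["namespace"] = element.get("namespace", "")
    attr_names = [a for a, _ in view.effective_attributes]
    declared = dict(view.effective_attributes)
    part_names = [p for p, _ in view.effective_has_parts + view.effective_hasa_parts]
    many = {p for p, _ in view.effective_has_parts}
    for child in element:
        article = child.get("articleName")
        if article is None:
            raise ParseError(f"child element {child.tag!r} lacks articleName")
        if child.tag in PRIMITIVE_PYTHON:
            name = _dearticle(article, attr_names)
            primitive = declared.get(name, child.tag)
            data.attributes[name] = _read_primitive(primitive, child.text)
        else:
            name = _dearticle(article, part_names)
            sub = _moby_from_element(engine, child)
            if name in many:
                data.parts.setdefault(name, []).append(sub)
            else:
                data.parts[name] = sub
    return data


def _parse_moby(engine: "DataEngine", content: bytes, target: str) -> StructuredData:
    try:
        root = etree.fromstring(content)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc
    from .taxonomy import is_subtype_of

    data = _moby_from_element(engine, root)
    if not is_subtype_of(engine.registry, data.datatype, target):
        raise ParseError(
            f"document carries {data.datatype!r}, not a subtype of {target!r}"
        )
    return data


# ---- the engine -----------------------------------------------------------------

class DataEngine:
    """Loader/formatter host bound to one registry's taxonomy.

    With ``defaults=True`` the shipped BioMOBY configuration is installed for
    whichever scope datatypes the taxonomy declares (loaders ``moby-base`` and
    ``sequence-length``; formatters fasta/raw/genbank/moby-xml).  Loaders can
    be disabled by name through the registry's persisted configuration.
    """

    def __init__(self, registry: Registry, defaults: bool = True) -> None:
        self.registry = registry
        self.loaders: dict[str, LoaderSpec] = {}
        self._loader_order: list[str] = []
        self.formatters: dict[str, FormatterSpec] = {}
        self._formatter_order: list[str] = []
        self.rules: list[FormatRule] = list(DEFAULT_RULES)
        if defaults:
            self.install_defaults()

    # -- plug-in registration ----------------------------------------------------

    def _scope_exists(self, name: str) -> bool:
        from .errors import NotFound

        try:
            self.registry.backend("datatype").get(name)
            return True
        except NotFound:
            return False

    def register_loader(self, spec: LoaderSpec) -> str:
        if spec.name in self.loaders:
            raise DuplicateName(f"loader {spec.name!r} already registered")
        if not self._scope_exists(spec.scope_datatype):
            raise UnresolvedReference(
                f"loader scope datatype {spec.scope_datatype!r} unknown"
            )
        self.loaders[spec.name] = spec
        self._loader_order.append(spec.name)
        return spec.name

    def register_formatter(self, spec: FormatterSpec) -> str:
        if spec.name in self.formatters:
            raise DuplicateName(f"formatter {spec.name!r} already registered")
        if not self._scope_exists(spec.scope_datatype):
            raise UnresolvedReference(
                f"formatter scope datatype {spec.scope_datatype!r} unknown"
            )
        self.formatters[spec.name] = spec
        self._formatter_order.append(spec.name)
        return spec.name

    def register_rule(self, rule: FormatRule) -> None:
        self.rules.append(rule)

    def set_loader_enabled(self, name: str, enabled: bool) -> None:
        disabled = set(self.registry.disabled_loaders)
        if enabled:
            disabled.discard(name)
        else:
            disabled.add(name)
        self.registry.disabled_loaders = sorted(disabled)

    def install_defaults(self) -> None:
        """Install the BioMOBY loader/formatter set for scopes the taxonomy has."""
        if self._scope_exists("Object"):
            if "moby-base" not in self.loaders:
                self.register_loader(
                    LoaderSpec("moby-base", "Object", _moby_base_transform, priority=0)
                )
            if "moby-xml:Object" not in self.formatters:
                self.register_formatter(
                    FormatterSpec("moby-xml", "Object", _parse_moby, _serialize_moby)
                )
        if self._scope_exists("GenericSequence"):
            if "sequence-length" not in self.loaders:
                self.register_loader(
                    LoaderSpec(
                        "sequence-length", "GenericSequence",
                        _sequence_length_transform, priority=0,
                    )
                )
            for spec in (
                FormatterSpec("fasta", "GenericSequence", _parse_fasta, _serialize_fasta),
                FormatterSpec("raw", "GenericSequence", _parse_raw, _serialize_raw),
                FormatterSpec("genbank", "GenericSequence", _parse_genbank, None, lossy=True),
            ):
                if spec.name not in self.formatters:
                    self.register_formatter(spec)

    # -- detection -----------------------------------------------------------------

    def detect_format(self, content: bytes) -> tuple[str, str]:
        """First matching rule by priority wins; ``("unknown", "n/a")`` if none."""
        if not content:
            raise EmptyInput("cannot detect the format of empty content")
        for rule in sorted(self.rules, key=lambda r: r.priority):
            if rule.matches(content):
                return rule.format_id, classify_alphabet(rule.sequence_region(content))
        return "unknown", "n/a"

    # -- parse / serialize -----------------------------------------------------------

    def _parse_formatter(self, format_id: str, target: str) -> FormatterSpec:
        from .taxonomy import is_subtype_of

        for name in self._formatter_order:
            spec = self.formatters[name]
            if (
                spec.format_id == format_id
                and spec.parse is not None
                and is_subtype_of(self.registry, target, spec.scope_datatype)
            ):
                return spec
        raise NoFormatter(f"no formatter parses {format_id!r} into {target!r}")

    def _serialize_formatter(self, format_id: str, datatype: str) -> FormatterSpec:
        from .taxonomy import is_subtype_of

        for name in self._formatter_order:
            spec = self.formatters[name]
            if (
                spec.format_id == format_id
                and spec.serialize is not None
                and is_subtype_of(self.registry, datatype, spec.scope_datatype)
            ):
                return spec
        raise NoFormatter(f"no formatter serializes {datatype!r} as {format_id!r}")

    def parse(self, content: bytes, format_id: str, target_datatype: str) -> StructuredData:
        """Parse wire content into a tree of the requested datatype.

        Loaders are *not* applied here; :meth:`apply_loaders` runs them.
        """
        self.registry.backend("datatype").get(target_datatype)
        spec = self._parse_formatter(format_id, target_datatype)
        if spec.lossy:
            warnings.warn(
                f"parsing {format_id!r} discards information the source carried",
                LossyFormatWarning,
                stacklevel=2,
            )
        data = spec.parse(self, content, target_datatype)
        data.provenance = format_id
        return data

    def serialize(self, data: StructuredData, format_id: str) -> bytes:
        spec = self._serialize_formatter(format_id, data.datatype)
        return spec.serialize(self, data)

    # -- loaders -------------------------------------------------------------------

    def loaders_in_scope(self, datatype: str) -> list[LoaderSpec]:
        """Enabled loaders whose scope is an ancestor-or-self of ``datatype``,
        ordered ancestor-first, then by priority, then registration order."""
        lineage = ancestors_or_self(self.registry, datatype)  # self first
        depth = {name: len(lineage) - 1 - i for i, name in enumerate(lineage)}
        disabled = set(self.registry.disabled_loaders)
        selected = [
            (depth[spec.scope_datatype], spec.priority, order, spec)
            for order, name in enumerate(self._loader_order)
            if (spec := self.loaders[name]).scope_datatype in depth
            and name not in disabled
        ]
        selected.sort(key=lambda item: item[:3])
        return [spec for *_, spec in selected]

    def apply_loaders(self, data: StructuredData) -> tuple[StructuredData, list[str]]:
        """Run every in-scope loader exactly once; returns the transformed copy
        and the loader names in execution order."""
        result = data.copy()
        applied: list[str] = []
        for spec in self.loaders_in_scope(data.datatype):
            try:
                result = spec.transform(self, result)
            except Exception as exc:
                raise LoaderFailure(spec.name, exc) from exc
            applied.append(spec.name)
        return result, applied

    # -- navigation ------------------------------------------------------------------

    def _declared(self, datatype: str):
        view = get_datatype(self.registry, datatype)
        attrs = dict(view.effective_attributes) | dict(UNIVERSAL_ATTRIBUTES)
        hasa = dict(view.effective_hasa_parts)
        has = dict(view.effective_has_parts)
        return attrs, hasa, has

    def get_part(self, data: StructuredData, path: str):
        """Value at a ``/``-separated path; :data:`MISSING` when declared but unset."""
        segments = [s for s in path.split("/") if s]
        if not segments:
            raise BadPath("empty path")
        current = data
        for i, segment in enumerate(segments):
            attrs, hasa, has = self._declared(current.datatype)
            last = i == len(segments) - 1
            if segment in attrs:
                if not last:
                    raise BadPath(f"attribute {segment!r} is not traversable")
                return current.attributes.get(segment, MISSING)
            if segment in hasa or segment in has:
                value = current.parts.get(segment, MISSING)
                if last:
                    return value
                if value is MISSING or isinstance(value, list):
                    raise BadPath(f"cannot traverse into part {segment!r}")
                current = value
                continue
            raise BadPath(
                f"{segment!r} is not a declared attribute or part of {current.datatype!r}"
            )
        return current

    def set_part(self, data: StructuredData, path: str, value: Any) -> StructuredData:
        """Set an attribute or part at a path, validating the declared type."""
        segments = [s for s in path.split("/") if s]
        if not segments:
            raise BadPath("empty path")
        current = data
        for segment in segments[:-1]:
            attrs, hasa, has = self._declared(current.datatype)
            if segment not in hasa:
                raise BadPath(f"cannot traverse into {segment!r}")
            nxt = current.parts.get(segment)
            if not isinstance(nxt, StructuredData):
                raise BadPath(f"part {segment!r} is unset")
            current = nxt
        leaf = segments[-1]
        attrs, hasa, has = self._declared(current.datatype)
        if leaf in attrs:
            expected = PRIMITIVE_PYTHON[attrs[leaf]]
            if expected is int and isinstance(value, bool):
                raise TypeMismatch(f"attribute {leaf!r} expects Integer, got Boolean")
            if expected is float and isinstance(value, int) and not isinstance(value, bool):
                value = float(value)
            if not isinstance(value, expected):
                raise TypeMismatch(
                    f"attribute {leaf!r} expects {attrs[leaf]}, got {type(value).__name__}"
                )
            current.attributes[leaf] = value
            return data
        if leaf in hasa or leaf in has:
            from .taxonomy import is_subtype_of

            declared_dt = hasa.get(leaf, has.get(leaf))
            values = value if isinstance(value, list) else [value]
            for sub in values:
                if not isinstance(sub, StructuredData) or not is_subtype_of(
                    self.registry, sub.datatype, declared_dt
                ):
                    raise TypeMismatch(
                        f"part {leaf!r} expects {declared_dt!r} instances"
                    )
            if leaf in has and not isinstance(value, list):
                value = [value]
            current.parts[leaf] = value
            return data
        raise BadPath(
            f"{leaf!r} is not a declared attribute or part of {current.datatype!r}"
        )

    # -- one-call conversion -----------------------------------------------------------

    def convert(
        self,
        content: bytes,
        target_format: str,
        target_datatype: str,
        source_format: str | None = None,
    ) -> ConversionResult:
        """detect -> parse -> apply loaders -> serialize, annotating failures
        with the stage that raised."""
        alphabet = "n/a"
        if source_format is None:
            try:
                source_format, alphabet = self.detect_format(content)
            except MobyKitError as exc:
                raise ConversionError("detect", exc) from exc
            if source_format == "unknown":
                raise ConversionError("detect", ParseError("unrecognized format"))
        try:
            data = self.parse(content, source_format, target_datatype)
        except MobyKitError as exc:
            raise ConversionError("parse", exc) from exc
        try:
            data, applied = self.apply_loaders(data)
        except MobyKitError as exc:
            raise ConversionError("load", exc) from exc
        try:
            out = self.serialize(data, target_format)
        except MobyKitError as exc:
            raise ConversionError("serialize", exc) from exc
        return ConversionResult(
            content=out,
            source_format=source_format,
            alphabet=alphabet,
            applied_loaders=applied,
            data=data,
        )
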