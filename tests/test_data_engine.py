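"""Structured data, loaders, formatters, detection and conversion."""

from __future__ import annotations

import random
import string

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from mobykit import (
    DataEngine,
    DatatypeNode,
    LoaderSpec,
    MISSING,
    StructuredData,
    add_datatype,
)
from mobykit.data_engine import FormatterSpec
from mobykit.errors import (
    BadPath,
    ConversionError,
    DuplicateName,
    EmptyInput,
    LossyFormatWarning,
    MissingAttribute,
    NoFormatter,
    ParseError,
    TypeMismatch,
)
from mobykit.fixtures import generate_random_taxonomy

# synthetic GenBank record (canonical flat-file layout)
GENBANK_RECORD = b"""LOCUS       TESTSEQ                    8 bp    DNA     linear   SYN 01-JAN-2020
DEFINITION  synthetic test record.
ACCESSION   TEST0001
VERSION     TEST0001.1
KEYWORDS    .
SOURCE      .
  ORGANISM  .
            .
FEATURES             Location/Qualifiers
     source          1..8
ORIGIN
        1 acgtacgt
//
"""


class TestDetection:
    @pytest.mark.parametrize(
        "content,expected",
        [
            (b">p1\nMKTAYIAK", ("fasta", "protein")),
            (b">n1\nACGTACGTAC", ("fasta", "nucleotide")),
            (GENBANK_RECORD, ("genbank", "nucleotide")),
            (b"ACGTACGTAC", ("raw", "nucleotide")),
            (b"MKTAYIAKQR", ("raw", "protein")),
            (b"@r1\nACGT\n+\nIIII\n", ("fastq", "nucleotide")),
            (b"<Object id=\"x\" namespace=\"\"/>", ("moby-xml", "n/a")),
            (b"{\"not\": \"sequence data\"}", ("unknown", "n/a")),
        ],
    )
    def test_rule_table(self, usecase_engine, content, expected):
        assert usecase_engine.detect_format(content) == expected

    def test_empty_input(self, usecase_engine):
        with pytest.raises(EmptyInput):
            usecase_engine.detect_format(b"")

    def test_alphabet_fraction_threshold(self, usecase_engine):
        """>=90% ACGTUN letters means nucleotide, below means protein."""
        rng = random.Random(0)
        for _ in range(50):
            n = rng.randint(20, 80)
            k = rng.randint(0, n)
            seq = "".join(
                rng.choice("ACGT") if i < k else rng.choice("MKWYFPE")
                for i in range(n)
            )
            fmt, alphabet = usecase_engine.detect_format(seq.encode())
            assert fmt == "raw"
            assert alphabet == ("nucleotide" if k / n >= 0.9 else "protein")


class TestParse:
    def test_fasta_parse_leaves_length_to_loaders(self, usecase_engine):
        data = usecase_engine.parse(b">s1\nMKT", "fasta", "GenericSequence")
        assert data.attributes == {"id": "s1", "SequenceString": "MKT"}
        assert "length" not in data.attributes
        assert data.provenance == "fasta"

    def test_genbank_parse_is_lossy(self, usecase_engine):
        with pytest.warns(LossyFormatWarning):
            data = usecase_engine.parse(GENBANK_RECORD, "genbank", "GenericSequence")
        assert data.attributes["SequenceString"] == "ACGTACGT"
        assert data.attributes["id"].startswith("TEST0001")

    def test_malformed_moby_xml(self, usecase_engine):
        with pytest.raises(ParseError):
            usecase_engine.parse(b"<GenericSequence", "moby-xml", "GenericSequence")

    def test_moby_xml_of_wrong_datatype(self, usecase_engine):
        doc = b'<BLAST-Text id="" namespace=""/>'
        with pytest.raises(ParseError):
            usecase_engine.parse(doc, "moby-xml", "GenericSequence")


class TestLoaders:
    def test_two_biomoby_loaders_run_seamlessly(self, usecase_engine):
        data = usecase_engine.parse(b"MKT", "raw", "GenericSequence")
        loaded, applied = usecase_engine.apply_loaders(data)
        assert applied == ["moby-base", "sequence-length"]
        assert loaded.attributes["id"] == ""
        assert loaded.attributes["namespace"] == ""
        assert loaded.attributes["length"] == 3

    def test_child_datatype_inherits_loaders(self, usecase_engine):
        data = StructuredData("AminoAcidSequence", {"SequenceString": "MKTA"})
        loaded, applied = usecase_engine.apply_loaders(data)
        assert applied == ["moby-base", "sequence-length"]
        assert loaded.attributes["length"] == 4

    def test_datatype_with_no_loaders_in_scope(self, usecase_registry):
        engine = DataEngine(usecase_registry)
        add_datatype(usecase_registry, DatatypeNode("Standalone"))
        data = StructuredData("Standalone")
        loaded, applied = engine.apply_loaders(data)
        assert applied == [] and loaded == data

    def test_registering_a_loader_extends_the_applied_list(self, usecase_engine):
        usecase_engine.register_loader(
            LoaderSpec(
                "uppercase",
                "GenericSequence",
                lambda eng, d: (
                    d.attributes.__setitem__(
                        "SequenceString", d.attributes["SequenceString"].upper()
                    )
                    or d
                ),
            )
        )
        data = StructuredData("GenericSequence", {"SequenceString": "mkt"})
        loaded, applied = usecase_engine.apply_loaders(data)
        assert applied == ["moby-base", "sequence-length", "uppercase"]
        assert loaded.attributes["SequenceString"] == "MKT"

    def test_duplicate_loader_name(self, usecase_engine):
        with pytest.raises(DuplicateName):
            usecase_engine.register_loader(
                LoaderSpec("moby-base", "Object", lambda eng, d: d)
            )

    def test_disable_loader_by_configuration(self, usecase_engine):
        usecase_engine.set_loader_enabled("sequence-length", False)
        data = StructuredData("GenericSequence", {"SequenceString": "MKT"})
        _, applied = usecase_engine.apply_loaders(data)
        assert applied == ["moby-base"]

    def test_apply_loaders_idempotent(self, usecase_engine):
        data = usecase_engine.parse(b">s\nMKTAYIAK", "fasta", "GenericSequence")
        once, _ = usecase_engine.apply_loaders(data)
        twice, _ = usecase_engine.apply_loaders(once)
        assert once == twice

    def test_loader_scoping_matches_closure_oracle(self):
        """Applied set == loaders whose scope is an ancestor-or-self, computed
        by an independent parent walk over a random taxonomy."""
        from mobykit import Registry

        rng = random.Random(31)
        registry = Registry(seed=31)
        names = generate_random_taxonomy(registry, rng, 25)
        engine = DataEngine(registry, defaults=False)
        scopes = rng.sample(names, 8)
        for i, scope in enumerate(scopes):
            engine.register_loader(LoaderSpec(f"L{i}", scope, lambda eng, d: d))
        parent = {n.name: n.is_parent for n in registry.backend("datatype").list()}
        for name in names:
            lineage = set()
            cur = name
            while cur is not None:
                lineage.add(cur)
                cur = parent[cur]
            expected = {
                f"L{i}" for i, scope in enumerate(scopes) if scope in lineage
            }
            _, applied = engine.apply_loaders(StructuredData(name))
            assert set(applied) == expected


class TestSerialize:
    def test_fasta_golden(self, usecase_engine):
        data = StructuredData(
            "GenericSequence",
            {"id": "s1", "namespace": "", "SequenceString": "MKT", "length": 3},
        )
        assert usecase_engine.serialize(data, "fasta") == b">s1\nMKT\n"

    def test_moby_xml_golden(self, usecase_engine):
        data = StructuredData(
            "GenericSequence",
            {"id": "s1", "namespace": "", "SequenceString": "MKT", "length": 3},
        )
        assert usecase_engine.serialize(data, "moby-xml") == (
            b'<GenericSequence id="s1" namespace="">'
            b'<Integer articleName="Length">3</Integer>'
            b'<String articleName="SequenceString">MKT</String>'
            b"</GenericSequence>"
        )

    def test_no_formatter_for_report_as_fasta(self, usecase_engine):
        data = StructuredData("BLAST-Text", {"content": "hits"})
        with pytest.raises(NoFormatter):
            usecase_engine.serialize(data, "fasta")

    def test_missing_attribute(self, usecase_engine):
        with pytest.raises(MissingAttribute):
            usecase_engine.serialize(StructuredData("GenericSequence"), "fasta")

    def test_moby_xml_parts_roundtrip(self, usecase_registry):
        engine = DataEngine(usecase_registry)
        add_datatype(
            usecase_registry,
            DatatypeNode(
                "SequenceSet",
                is_parent="Object",
                has_parts=[("members", "GenericSequence")],
            ),
        )
        data = StructuredData(
            "SequenceSet",
            {"id": "set1", "namespace": ""},
            parts={
                "members": [
                    StructuredData(
                        "GenericSequence",
                        {"id": "a", "namespace": "", "SequenceString": "MK", "length": 2},
                    ),
                    StructuredData(
                        "AminoAcidSequence",
                        {"id": "b", "namespace": "", "SequenceString": "TY", "length": 2},
                    ),
                ]
            },
        )
        wire = engine.serialize(data, "moby-xml")
        back = engine.parse(wire, "moby-xml", "SequenceSet")
        back.provenance = None
        assert back == data


class TestRoundTrips:
    @given(
        st.text(alphabet=string.ascii_uppercase, min_size=1, max_size=200),
        st.text(alphabet=string.ascii_letters + string.digits + "_.|", max_size=20),
    )
    @settings(
        max_examples=150,
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    def test_fasta_and_moby_roundtrip_and_length_loader(
        self, usecase_engine, sequence, identifier
    ):
        data = StructuredData(
            "GenericSequence", {"id": identifier, "SequenceString": sequence}
        )
        back = usecase_engine.parse(
            usecase_engine.serialize(data, "fasta"), "fasta", "GenericSequence"
        )
        back.provenance = None
        assert back == data

        loaded, _ = usecase_engine.apply_loaders(data)
        assert loaded.attributes["length"] == len(sequence)
        wire = usecase_engine.serialize(loaded, "moby-xml")
        back = usecase_engine.parse(wire, "moby-xml", "GenericSequence")
        back.provenance = None
        assert back == loaded

    def test_raw_roundtrip(self, usecase_engine):
        data = StructuredData("GenericSequence", {"SequenceString": "MKTAYIAK"})
        back = usecase_engine.parse(
            usecase_engine.serialize(data, "raw"), "raw", "GenericSequence"
        )
        back.provenance = None
        assert back == data


class TestNavigation:
    @pytest.fixture
    def seq(self, usecase_engine):
        data = usecase_engine.parse(b">s1\nMKT", "fasta", "GenericSequence")
        loaded, _ = usecase_engine.apply_loaders(data)
        return loaded

    def test_get_attribute(self, usecase_engine, seq):
        assert usecase_engine.get_part(seq, "SequenceString") == "MKT"

    def test_get_absent_declared_attribute(self, usecase_engine):
        data = StructuredData("GenericSequence", {"SequenceString": "MKT"})
        assert usecase_engine.get_part(data, "length") is MISSING

    def test_set_wrong_primitive(self, usecase_engine, seq):
        with pytest.raises(TypeMismatch):
            usecase_engine.set_part(seq, "length", "abc")

    def test_set_then_get(self, usecase_engine, seq):
        usecase_engine.set_part(seq, "length", 42)
        assert usecase_engine.get_part(seq, "length") == 42

    def test_undeclared_path(self, usecase_engine, seq):
        with pytest.raises(BadPath):
            usecase_engine.get_part(seq, "nonexistent")


class TestConvert:
    def test_raw_to_moby_xml(self, usecase_engine):
        result = usecase_engine.convert(b"MKTAYIAK", "moby-xml", "GenericSequence")
        assert result.source_format == "raw"
        assert result.applied_loaders == ["moby-base", "sequence-length"]
        assert b'<Integer articleName="Length">8</Integer>' in result.content

    def test_fasta_roundtrip_preserves_id_and_sequence(self, usecase_engine):
        original = b">seq1 a description\nMKTAYIAK\nMKT\n"
        result = usecase_engine.convert(original, "fasta", "GenericSequence")
        assert result.content == b">seq1\nMKTAYIAKMKT\n"  # canonical unwrapped form
        again = usecase_engine.convert(result.content, "fasta", "GenericSequence")
        assert again.content == result.content

    def test_genbank_conversion_cannot_reverse(self, usecase_engine):
        with pytest.warns(LossyFormatWarning):
            result = usecase_engine.convert(
                GENBANK_RECORD, "fasta", "GenericSequence"
            )
        assert result.content.startswith(b">TEST0001")
        with pytest.raises(ConversionError) as err:
            usecase_engine.convert(result.content, "genbank", "GenericSequence")
        assert err.value.stage == "serialize"
        assert isinstance(err.value.cause, NoFormatter)

    def test_unknown_format_annotates_detect_stage(self, usecase_engine):
        with pytest.raises(ConversionError) as err:
            usecase_engine.convert(b"{}", "fasta", "GenericSequence")
        assert err.value.stage == "detect"

    def test_registering_a_formatter(self, usecase_engine):
        usecase_engine.register_formatter(
            FormatterSpec(
                "plain",
                "BLAST-Text",
                serialize=lambda eng, d: d.attributes.get("content", "").encode(),
            )
        )
        data = StructuredData("BLAST-Text", {"content": "report body"})
        assert usecase_engine.serialize(data, "plain") == b"report body"
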