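"""Parsing, decomposition, and lookup against the normalized store."""

from __future__ import annotations

import io

import pytest

import semgo
from semgo import (
    DuplicateTermError,
    NormalizedStore,
    OboFormatError,
    OboStanzaError,
    OntTerm,
    Relation,
    Synonym,
    decompose,
    parse_obo,
)
from semgo.ontology_store import NAMESPACES

from conftest import TINY_OBO


class TestParseObo:
    def test_empty_stream_gives_empty_list(self):
        assert parse_obo("") == []
        assert parse_obo(io.StringIO("")) == []

    def test_tiny_fixture_counts_and_namespaces(self, tiny_terms):
        assert len(tiny_terms) == 10
        by_ns = {ns: [t for t in tiny_terms if t.namespace == ns] for ns in NAMESPACES}
        assert len(by_ns["cellular_component"]) == 4
        assert len(by_ns["molecular_function"]) == 3
        assert len(by_ns["biological_process"]) == 3
        assert sum(t.obsolete for t in tiny_terms) == 1

    def test_binding_stanza_worked_record(self, core_obo):
        terms = {t.term_id: t for t in parse_obo(core_obo)}
        binding = terms["GO:0005488"]
        assert binding.name == "binding"
        assert binding.namespace == "molecular_function"
        assert binding.synonyms == [Synonym("ligand", "NARROW")]
        assert binding.relations == [
            Relation("GO:0003674", "molecular_function", "is_a")
        ]
        assert not binding.obsolete

    def test_malformed_stanza_raises_record_level_error(self):
        bad = TINY_OBO + "\n[Term]\nname: nameless orphan\n"
        with pytest.raises(OboStanzaError) as exc:
            parse_obo(bad)
        assert "nameless orphan" in str(exc.value)

    def test_non_obo_input_raises_format_error(self):
        with pytest.raises(OboFormatError):
            parse_obo("this is just prose\nwith two lines\n")

    def test_relation_target_name_resolved_from_sibling_stanza(self):
        # no "! name" comment: the name must come from the target's stanza
        text = (
            "format-version: 1.2\n\n[Term]\nid: X:1\nname: parent thing\n"
            "namespace: biological_process\n\n[Term]\nid: X:2\nname: child thing\n"
            "namespace: biological_process\nis_a: X:1\n"
        )
        terms = {t.term_id: t for t in parse_obo(text)}
        assert terms["X:2"].relations == [Relation("X:1", "parent thing", "is_a")]

    def test_regulates_subtypes_folded_and_unknown_scopes_dropped(self):
        text = (
            "format-version: 1.2\n\n[Term]\nid: X:1\nname: base\n"
            "namespace: biological_process\n\n[Term]\nid: X:2\nname: reg\n"
            "namespace: biological_process\n"
            "relationship: positively_regulates X:1 ! base\n"
            "relationship: occurs_in X:1 ! base\n"
            'synonym: "sic typo" RELATD []\n'
            'synonym: "weird scope" SYSTEMATIC []\n'
        )
        terms = {t.term_id: t for t in parse_obo(text)}
        assert terms["X:2"].relations == [Relation("X:1", "base", "regulates")]
        assert terms["X:2"].synonyms == [Synonym("sic typo", "RELATED")]


class TestDecompose:
    def test_partition_routes_by_namespace_and_skips_obsolete(self, tiny_store):
        counts = tiny_store.counts()
        # 4 cc minus the obsolete one, 3 mf, 3 bp
        assert (counts["component"], counts["function"], counts["process"]) == (3, 3, 3)

    def test_empty_term_list_gives_empty_tables(self):
        store = decompose([])
        counts = store.counts()
        assert all(
            counts[t] == 0
            for t in ("component", "function", "process", "synonym", "relation")
        )

    def test_binding_lands_in_function_table_with_synonym(self, core_store):
        row = core_store.conn.execute(
            "SELECT FID, FName FROM function WHERE FID = 'GO:0005488'"
        ).fetchone()
        assert row == ("GO:0005488", "binding")
        syn = core_store.conn.execute(
            "SELECT GID, SName, SType FROM synonym WHERE GID = 'GO:0005488'"
        ).fetchall()
        assert syn == [("GO:0005488", "ligand", "NARROW")]

    def test_duplicate_term_id_raises_naming_the_id(self):
        t = OntTerm("X:1", "thing", "biological_process")
        with pytest.raises(DuplicateTermError, match="X:1"):
            decompose([t, t])

    def test_closed_vocabularies_in_stored_tables(self, core_store):
        stypes = {
            r[0] for r in core_store.conn.execute("SELECT DISTINCT SType FROM synonym")
        }
        rtypes = {
            r[0] for r in core_store.conn.execute("SELECT DISTINCT RType FROM relation")
        }
        assert stypes <= set(semgo.SYNONYM_SCOPES)
        assert rtypes <= set(semgo.RELATION_TYPES)

    def test_every_gid_keys_to_a_stored_term(self, tiny_store):
        stored = set(tiny_store.all_term_ids())
        for table in ("synonym", "relation"):
            gids = {
                r[0] for r in tiny_store.conn.execute(f"SELECT GID FROM {table}")
            }
            assert gids <= stored

    def test_in_memory_and_file_stores_answer_identically(self, tmp_path, core_obo):
        terms = parse_obo(core_obo)
        mem = decompose(terms)
        disk = decompose(terms, tmp_path / "store.db")
        for probe in ("binding", "chromosome", "GO:0040007", "no-such-term"):
            assert mem.lookup_term(probe) == disk.lookup_term(probe)
        assert mem.vocabulary() == disk.vocabulary()
        # reopening the file artifact must preserve the answers
        reopened = NormalizedStore(tmp_path / "store.db")
        assert reopened.lookup_term("binding") == mem.lookup_term("binding")

    def test_tsv_dump_columns_and_determinism(self, tmp_path, core_store):
        a = core_store.dump_tsv(tmp_path / "a")
        b = core_store.dump_tsv(tmp_path / "b")
        for pa, pb in zip(a, b):
            assert pa.read_bytes() == pb.read_bytes()
        header = (tmp_path / "a" / "relation.tsv").read_text().splitlines()[0]
        assert header == "RID\tGID\tParentID\tParentName\tRType"


class TestLookup:
    def test_binding_metadata_block(self, core_store):
        recs = core_store.lookup_term("binding")
        assert len(recs) == 1
        rec = recs[0]
        assert rec.term_id == "GO:0005488"
        assert rec.type_label == "Function"
        assert rec.synonyms == [Synonym("ligand", "NARROW")]
        assert [(r.target_name, r.rel_type) for r in rec.relations] == [
            ("molecular_function", "is_a")
        ]

    def test_chromosome_printed_record(self, core_store):
        rec = core_store.lookup_term("chromosome")[0]
        assert {(s.surface, s.scope) for s in rec.synonyms} == {
            ("chromatid", "RELATED"),
            ("interphase chromosome", "NARROW"),
            ("prophase chromosome", "NARROW"),
        }
        assert [(r.target_name, r.rel_type) for r in rec.relations] == [
            ("intracellular non-membrane-bounded organelle", "is_a")
        ]

    def test_lookup_is_case_insensitive_and_accepts_ids(self, core_store):
        assert core_store.lookup_term("BINDING")[0].term_id == "GO:0005488"
        assert core_store.lookup_term("GO:0005488")[0].name == "binding"

    def test_missing_term_gives_empty_result_not_error(self, core_store):
        assert core_store.lookup_term("no-such-term") == []

    def test_roundtrip_matches_reparse(self, core_obo, core_store):
        """Stored synonyms/relations equal those of a brute re-parse."""
        for term in parse_obo(core_obo):
            if term.obsolete:
                continue
            rec = core_store.lookup_term(term.term_id)[0]
            assert rec.synonyms == term.synonyms
            assert rec.relations == term.relations


class TestObonetCrossCheck:
    """Independent parse of the fixture OBO through obonet."""

    def test_ids_names_namespaces_agree(self, core_obo):
        obonet = pytest.importorskip("obonet")
        graph = obonet.read_obo(io.StringIO(core_obo))
        ours = {
            t.term_id: t for t in parse_obo(core_obo) if not t.obsolete
        }
        assert set(graph.nodes) == set(ours)
        for node, data in graph.nodes(data=True):
            assert data["name"] == ours[node].name
            assert data["namespace"] == ours[node].namespace
            n_syn = len(data.get("synonym", []))
            assert n_syn == len(ours[node].synonyms)

    def test_isa_edges_agree(self, core_obo):
        obonet = pytest.importorskip("obonet")
        graph = obonet.read_obo(io.StringIO(core_obo))
        theirs = {
            (child, parent)
            for child, parent, key in graph.edges(keys=True)
            if key == "is_a"
        }
        ours = {
            (t.term_id, r.target_id)
            for t in parse_obo(core_obo)
            for r in t.relations
            if r.rel_type == "is_a" and not t.obsolete
        }
        assert theirs == ours
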