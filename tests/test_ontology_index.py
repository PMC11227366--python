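"""Ontology parsing, surface processing, and the signature index."""

import io
import json

import pytest

from ontosig.cluster_vocab import load_clusters
from ontosig.ontology_index import (
    Concept,
    MissReport,
    build_index,
    consolidate,
    default_blacklist,
    filter_blacklist,
    load_index,
    make_signature,
    parse_ontology,
    save_index,
    tokenize_surface,
)

MINI_OBO = """\
format-version: 1.2
ontology: mini

[Term]
id: HP:0000256
name: Macrocephaly
alt_id: HP:0001355
synonym: "Increased size of cranium" EXACT []
synonym: "Big head" RELATED []

[Term]
id: HP:0100790
name: Hernia

[Term]
id: HP:0009999
name: obsolete Big cranium
is_obsolete: true
replaced_by: HP:0000256
"""

MINI_OBOGRAPHS = {
    "graphs": [
        {
            "nodes": [
                {
                    "id": "http://purl.obolibrary.org/obo/HP_0000256",
                    "lbl": "Macrocephaly",
                    "type": "CLASS",
                    "meta": {
                        "synonyms": [
                            {"pred": "hasExactSynonym", "val": "Increased size of cranium"},
                            {"pred": "hasRelatedSynonym", "val": "Big head"},
                        ],
                        "basicPropertyValues": [
                            {
                                "pred": "http://www.geneontology.org/formats/oboInOwl#hasAlternativeId",
                                "val": "HP:0001355",
                            }
                        ],
                    },
                },
                {
                    "id": "http://purl.obolibrary.org/obo/HP_0100790",
                    "lbl": "Hernia",
                    "type": "CLASS",
                },
                {
                    "id": "http://purl.obolibrary.org/obo/HP_0009999",
                    "lbl": "obsolete Big cranium",
                    "type": "CLASS",
                    "meta": {
                        "deprecated": True,
                        "basicPropertyValues": [
                            {
                                "pred": "http://purl.obolibrary.org/obo/IAO_0100001",
                                "val": "http://purl.obolibrary.org/obo/HP_0000256",
                            }
                        ],
                    },
                },
            ]
        }
    ]
}
# IAO:0100001 is "term replaced by"; the suffix check keys on the pred name
MINI_OBOGRAPHS["graphs"][0]["nodes"][2]["meta"]["basicPropertyValues"][0][
    "pred"
] = "http://purl.obolibrary.org/obo/terms/term_replaced_by"


class TestParseOntology:
    def test_obo_roundtrip_fields(self, tmp_path):
        p = tmp_path / "mini.obo"
        p.write_text(MINI_OBO)
        concepts = {c.concept_id: c for c in parse_ontology(p)}
        assert len(concepts) == 3
        macro = concepts["HP:0000256"]
        assert macro.label == "Macrocephaly"
        assert macro.synonyms == ["Increased size of cranium", "Big head"]
        assert macro.synonym_scopes == ["EXACT", "RELATED"]
        assert macro.alt_ids == ["HP:0001355"]
        assert not macro.obsolete
        obs = concepts["HP:0009999"]
        assert obs.obsolete and obs.replaced_by == "HP:0000256"

    def test_obographs_equals_obo(self, tmp_path):
        obo = tmp_path / "mini.obo"
        obo.write_text(MINI_OBO)
        og = tmp_path / "mini.json"
        og.write_text(json.dumps(MINI_OBOGRAPHS))
        a = sorted(parse_ontology(obo), key=lambda c: c.concept_id)
        b = sorted(parse_ontology(og), key=lambda c: c.concept_id)
        for ca, cb in zip(a, b):
            assert (ca.concept_id, ca.label, ca.synonyms, ca.alt_ids,
                    ca.obsolete, ca.replaced_by) == (
                cb.concept_id, cb.label, cb.synonyms, cb.alt_ids,
                cb.obsolete, cb.replaced_by)

    def test_unparseable_file(self, tmp_path):
        p = tmp_path / "broken.json"
        p.write_text("{not json")
        with pytest.raises(ValueError, match="cannot parse"):
            parse_ontology(p, fmt="obographs-json")


@pytest.mark.parametrize(
    "text, expected",
    [
        ("Increased size of cranium", ["increased", "size", "of", "cranium"]),
        ("", []),
        ("cleft lip/palate", ["cleft", "lip", "palate"]),
        ("Short stature, severe", ["short", "stature", "severe"]),
        ("Type 1 diabetes", ["type", "1", "diabetes"]),
    ],
)
def test_tokenize_surface(text, expected):
    assert tokenize_surface(text) == expected


@pytest.mark.parametrize(
    "tokens, expected",
    [
        (["increased", "size", "of", "cranium"], ["increased", "size", "cranium"]),
        (["of", "the"], []),
        (["short", "and", "broad", "toes"], ["short", "broad", "toes"]),
    ],
)
def test_filter_blacklist(tokens, expected):
    assert filter_blacklist(tokens, default_blacklist()) == expected


class TestConsolidate:
    def test_worked_example(self, cranium_vocab):
        assert consolidate(["increased", "size", "cranium"], cranium_vocab) == [
            "C2", "C26", "C35",
        ]

    def test_empty(self, cranium_vocab):
        assert consolidate([], cranium_vocab) == []

    def test_uncovered_token_reported(self, cranium_vocab):
        result = consolidate(["increased", "zzz"], cranium_vocab)
        assert isinstance(result, MissReport)
        assert result.missing == ["zzz"]

    def test_numeric_token_gets_implicit_cluster(self, cranium_vocab):
        assert consolidate(["size", "1"], cranium_vocab) == ["C26", "1"]


class TestMakeSignature:
    def test_lexicographic_key(self):
        sig = make_signature(["C3425", "C112", "C59"])
        assert sig.key == "C112-C3425-C59"
        assert sig.length == 3

    def test_worked_example_key(self):
        sig = make_signature(["C2", "C26", "C35"])
        assert sig.key == "C2-C26-C35"
        assert sig.length == 3

    def test_duplicate_cluster_collapses_key_keeps_length(self):
        sig = make_signature(["C7", "C7"])
        assert sig.key == "C7"
        assert sig.length == 2

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError, match="empty surface"):
            make_signature([])


class TestBuildIndex:
    def test_worked_example(self, cranium_index):
        entries = cranium_index.signature_map[("C2-C26-C35", 3)]
        assert [(e.concept_id, e.surface, e.is_label) for e in entries] == [
            ("HP:0000256", "Increased size of cranium", False)
        ]

    def test_empty_concepts(self, cranium_vocab):
        index = build_index([], cranium_vocab)
        assert index.signature_map == {}
        assert index.token_map == {}

    def test_signature_collision_keeps_both(self, cranium_vocab):
        concepts = [
            Concept("X:1", "Increased size of cranium"),
            Concept("X:2", "Size increase of the cranium"),
        ]
        index = build_index(concepts, cranium_vocab)
        entries = index.signature_map[("C2-C26-C35", 3)]
        assert {e.concept_id for e in entries} == {"X:1", "X:2"}

    def test_variant_closure(self, cranium_vocab, cranium_index):
        # every member of every used cluster is in the token map, even the
        # variants no indexed surface mentions
        assert cranium_index.lookup_token("increasing") == "C2"
        assert cranium_index.lookup_token("sizes") == "C26"
        assert cranium_index.lookup_token("crania") == "C35"
        by_id = {c.cluster_id: c for c in cranium_vocab.clusters}
        for cid in set(cranium_index.token_map.values()):
            for member in by_id[cid].members:
                assert cranium_index.lookup_token(member) == cid

    def test_no_tokens_outside_closure(self, cranium_index):
        # filler clusters from unrelated lines must not leak into the index
        assert cranium_index.lookup_token("fillerab") is None
        used = set(cranium_index.token_map.values())
        # C3 is the label's own cluster ("macrocephaly")
        assert used == {"C2", "C3", "C26", "C35"}

    def test_unindexable_and_empty_surfaces_are_skipped(self, cranium_vocab):
        concepts = [
            Concept("X:1", "Totally unknown words"),
            Concept("X:2", "Of the"),
            Concept("X:3", "Macrocephaly"),
        ]
        index = build_index(concepts, cranium_vocab)
        assert index.n_indexed == 1
        skipped = {cid for cid, _, _ in index.skipped_surfaces}
        assert skipped == {"X:1", "X:2"}

    def test_obsolete_concepts_not_indexed_but_alignable(self, cranium_vocab):
        concepts = [
            Concept("X:1", "Macrocephaly", alt_ids=["X:9"]),
            Concept("X:8", "Increased size of cranium", obsolete=True,
                    replaced_by="X:1"),
        ]
        index = build_index(concepts, cranium_vocab)
        assert all(e.concept_id == "X:1" for b in index.signature_map.values() for e in b)
        assert index.alt_id_map == {"X:9": "X:1", "X:8": "X:1"}


class TestIndexSerialization:
    def test_round_trip(self, cranium_index, tmp_path):
        p = tmp_path / "index.json"
        save_index(cranium_index, p)
        loaded = load_index(p)
        assert loaded.token_map == cranium_index.token_map
        assert loaded.signature_map == cranium_index.signature_map
        assert loaded.blacklist == cranium_index.blacklist
        assert loaded.alt_id_map == cranium_index.alt_id_map

    def test_truncated_file(self, tmp_path):
        p = tmp_path / "index.json"
        p.write_text('{"schema_version": "1", "token_map": {')
        with pytest.raises(ValueError, match="corrupt"):
            load_index(p)

    def test_schema_version_mismatch(self, tmp_path):
        p = tmp_path / "index.json"
        p.write_text(json.dumps({"schema_version": "99", "signatures": [],
                                 "token_map": {}, "blacklist": []}))
        with pytest.raises(ValueError, match="schema version mismatch"):
            load_index(p)

    def test_rebuild_is_byte_identical(self, cranium_vocab, tmp_path):
        concepts = [
            Concept("HP:0000256", "Macrocephaly",
                    ["Increased size of cranium"], ["EXACT"]),
        ]
        files = []
        for name in ("a.json", "b.json"):
            index = build_index(concepts, cranium_vocab, ontology_version="v")
            index.metadata["built"] = "fixed"  # timestamp is the only nondeterminism
            save_index(index, tmp_path / name)
            files.append((tmp_path / name).read_bytes())
        assert files[0] == files[1]


def test_token_order_invariance_of_signature(cranium_vocab):
    import itertools

    ids = consolidate(["increased", "size", "cranium"], cranium_vocab)
    signatures = {
        make_signature(list(perm)) for perm in itertools.permutations(ids)
    }
    assert len(signatures) == 1
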