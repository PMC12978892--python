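"""Concept catalog loading, map-table model, lexical matching."""

import pytest

from uit.mapping import (
    FSN_TYPE_ID,
    SYNONYM_TYPE_ID,
    ConceptCatalog,
    Description,
    MapEntry,
    MapTable,
    MappingError,
    classify_term_language,
    detect_direct_lexical_match,
    lexical_key,
    load_concept_catalog,
    load_map_table,
    write_concept_catalog,
    write_map_table,
)

RF2_HEADER = "id\teffectiveTime\tactive\tmoduleId\tconceptId\tlanguageCode\ttypeId\tterm\tcaseSignificanceId\n"


def write_rf2(path, rows):
    lines = [RF2_HEADER]
    for r in rows:
        lines.append("\t".join(r) + "\n")
    path.write_text("".join(lines), encoding="utf-8")
    return path


class TestConceptCatalog:
    def test_fsn_and_synonym_build_one_concept(self, tmp_path):
        path = write_rf2(
            tmp_path / "d.tsv",
            [
                ("101", "20240101", "1", "0", "900101", "en", FSN_TYPE_ID,
                 "Nodule of lung (disorder)", "0"),
                ("102", "20240101", "1", "0", "900101", "en", SYNONYM_TYPE_ID,
                 "Lung nodule", "0"),
            ],
        )
        catalog = load_concept_catalog(path)
        assert len(catalog.concepts) == 1
        assert len(catalog.descriptions) == 2
        assert catalog.concepts["900101"].semantic_tag == "disorder"

    def test_inactive_rows_dropped_and_counted(self, tmp_path):
        path = write_rf2(
            tmp_path / "d.tsv",
            [
                ("101", "20240101", "1", "0", "900101", "en", SYNONYM_TYPE_ID, "a", "0"),
                ("102", "20240101", "0", "0", "900101", "en", SYNONYM_TYPE_ID, "b", "0"),
            ],
        )
        catalog = load_concept_catalog(path)
        assert len(catalog.descriptions) == 1
        assert catalog.n_inactive_dropped == 1

    def test_missing_column_error_names_it(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("id\tactive\tterm\nx\t1\ty\n", encoding="utf-8")
        with pytest.raises(MappingError, match="conceptId"):
            load_concept_catalog(path)

    def test_synthetic_catalog_round_trips(self, tmp_path, study_run):
        study, _, _ = study_run
        path = tmp_path / "d.tsv"
        write_concept_catalog(study.catalog, path)
        back = load_concept_catalog(path)
        assert {d.term for d in back.descriptions} == {
            d.term for d in study.catalog.descriptions
        }
        assert set(back.concepts) == set(study.catalog.concepts)


def mapped(term, cid, eq="full", lang="english", n=1):
    return MapEntry(term, lang, n, cid, eq, "contextual")


def unmapped(term, cat="ambiguous", lang="english", n=1):
    return MapEntry(term, lang, n, None, "unmapped", "none", cat)


class TestMapTable:
    def test_unmapped_row_loads(self, tmp_path):
        path = tmp_path / "m.csv"
        write_map_table(MapTable([unmapped("lobe")]), path)
        [entry] = load_map_table(path).entries
        assert entry.equivalence == "unmapped" and entry.target_concept_id is None

    def test_one_to_many_counts_pairs(self):
        table = MapTable([mapped("fundus", "1"), mapped("fundus", "2", "broader")])
        acc = table.accounting()
        assert acc["n_one_to_many_terms"] == 1
        assert acc["n_one_to_many_pairs"] == 2
        assert acc["n_one_to_one_terms"] == 0

    def test_round_trip_on_synthetic_gold_map(self, tmp_path, study_run):
        study, _, _ = study_run
        path = tmp_path / "m.csv"
        write_map_table(study.gold_map, path)
        assert load_map_table(path).entries == study.gold_map.entries

    def test_unknown_relationship_is_error(self, tmp_path):
        path = tmp_path / "m.csv"
        write_map_table(MapTable([mapped("x", "1")]), path)
        path.write_text(
            path.read_text(encoding="utf-8").replace("TARGET_EQUIVALENT", "WAT"),
            encoding="utf-8",
        )
        with pytest.raises(MappingError, match="relationship"):
            load_map_table(path)

    def test_term_cannot_be_mapped_and_unmapped(self):
        with pytest.raises(MappingError):
            MapTable([mapped("x", "1"), unmapped("x")])

    def test_inconsistent_entry_rejected(self):
        with pytest.raises(MappingError):
            MapEntry("x", "english", 1, "123", "unmapped", "none")
        with pytest.raises(MappingError):
            MapEntry("x", "english", 1, None, "full", "contextual")

    def test_entry_accounting_identity(self, study_run):
        study, _, _ = study_run
        acc = study.gold_map.accounting()
        assert acc["n_entries"] == (
            acc["n_one_to_one_terms"]
            + acc["n_one_to_many_pairs"]
            + acc["n_unmapped_terms"]
        )
        assert acc["n_unique_concepts"] <= acc["n_entries"] - acc["n_unmapped_terms"]


class TestTermLanguage:
    @pytest.mark.parametrize(
        "term,lang",
        [
            ("อาเจียนเป็นเลือด", "thai"),
            ("wound dressing", "english"),
            ("ct ปอด", "thai"),  # mixed script counts as thai
        ],
    )
    def test_script_rule(self, term, lang):
        assert classify_term_language(term) == lang

    def test_empty_is_error(self):
        with pytest.raises(MappingError):
            classify_term_language("")


class TestDirectLexicalMatch:
    def catalog(self):
        cat = ConceptCatalog()
        cat.add(Description("1", "c1", "Dressing wound"))
        cat.add(Description("2", "c2", "Follow-up visit"))
        cat.add(Description("3", "c3", "Exposure to tuberculosis"))
        return cat

    def test_word_order_variation_matches(self):
        hit, desc_id = detect_direct_lexical_match("wound dressing", self.catalog())
        assert hit and desc_id == "1"

    def test_abbreviation_is_not_lexical_match(self):
        hit, _ = detect_direct_lexical_match("f/u", self.catalog())
        assert not hit

    def test_writing_style_variation_is_not_lexical_match(self):
        hit, _ = detect_direct_lexical_match("contact tb", self.catalog())
        assert not hit

    def test_identical_strings_match(self):
        hit, _ = detect_direct_lexical_match("Exposure to tuberculosis", self.catalog())
        assert hit

    def test_inactive_descriptions_not_matched(self):
        cat = ConceptCatalog()
        cat.add(Description("1", "c1", "Dressing wound", active=False))
        hit, _ = detect_direct_lexical_match("wound dressing", cat)
        assert not hit

    def test_key_symmetric_and_reflexive(self):
        assert lexical_key("Wound, dressing") == lexical_key("dressing WOUND")
        assert lexical_key("x y") == lexical_key("x y")
        # multiset, not set: repeated words matter
        assert lexical_key("x x y") != lexical_key("x y")
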