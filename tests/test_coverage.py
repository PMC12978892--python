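"""Coverage statistics against brute-force recounts and printed arithmetic."""

import random
from collections import Counter

import pytest

from uit.coverage import (
    CoverageError,
    concept_coverage,
    full_report,
    render_report,
    term_coverage,
    unmapped_breakdown,
)
from uit.mapping import (
    ConceptCatalog,
    Description,
    MapEntry,
    MapTable,
    UNMAPPED_CATEGORIES,
)
from uit._text import pct


def mapped(term, cid, eq="full", lang="english", n=1):
    return MapEntry(term, lang, n, cid, eq, "contextual")


def unmapped(term, cat="ambiguous", lang="english", n=1):
    return MapEntry(term, lang, n, None, "unmapped", "none", cat)


def table_from_counts(counts):
    """counts: {equivalence: n} -> synthetic single-language table."""
    entries = []
    i = 0
    for eq, n in counts.items():
        for _ in range(n):
            if eq == "unmapped":
                entries.append(unmapped(f"t{i}"))
            else:
                entries.append(mapped(f"t{i}", str(i), eq))
            i += 1
    return MapTable(entries)


class TestConceptCoverage:
    def test_printed_equivalence_counts_reproduce_percentages(self):
        table = table_from_counts(
            {"full": 1781, "broader": 123, "narrower": 56, "inexact": 81, "unmapped": 42}
        )
        report = concept_coverage(table)
        assert report.n_entries == 2083
        assert report.concept_coverage_full == 85.50
        assert report.concept_coverage_full_plus_partial == 97.98
        assert report.unmapped_percent == 2.02
        assert report.by_equivalence["broader"]["total"].percent == 5.90
        assert report.by_equivalence["narrower"]["total"].percent == 2.69
        assert report.by_equivalence["inexact"]["total"].percent == 3.89

    def test_single_fully_mapped_entry(self):
        report = concept_coverage(MapTable([mapped("x", "1")]))
        assert report.concept_coverage_full == 100.00

    def test_empty_table_is_error(self):
        with pytest.raises(CoverageError):
            concept_coverage(MapTable([]))

    def test_random_table_matches_brute_force_recount(self):
        rng = random.Random(17)
        entries = []
        for i in range(500):
            lang = rng.choice(["english", "thai"])
            eq = rng.choice(["full", "broader", "narrower", "inexact", "unmapped"])
            if eq == "unmapped":
                entries.append(unmapped(f"t{i}", rng.choice(UNMAPPED_CATEGORIES), lang))
            else:
                entries.append(mapped(f"t{i}", str(rng.randint(1, 60)), eq, lang))
        table = MapTable(entries)
        report = concept_coverage(table)
        recount = Counter((e.equivalence, e.source_language) for e in entries)
        n = len(entries)
        for eq in ("full", "broader", "narrower", "inexact", "unmapped"):
            for lang in ("english", "thai"):
                cell = report.by_equivalence[eq][lang]
                assert cell.count == recount[(eq, lang)]
                assert cell.percent == pct(recount[(eq, lang)], n)
        assert report.n_unique_concepts == len(
            {e.target_concept_id for e in entries if e.target_concept_id}
        )

    def test_category_and_language_counts_conserve_entries(self, study_run):
        study, _, _ = study_run
        report = concept_coverage(study.gold_map)
        n = report.n_entries
        assert (
            sum(
                report.by_equivalence[eq]["total"].count
                for eq in ("full", "broader", "narrower", "inexact", "unmapped")
            )
            == n
        )
        assert (
            report.language_totals["english"].count
            + report.language_totals["thai"].count
            == n
        )

    def test_gold_map_reproduces_designed_fractions_exactly(self, study_run):
        study, _, expected = study_run
        report = concept_coverage(study.gold_map)
        designed = study.bookkeeping["equivalence_counts"]
        for eq, count in designed.items():
            assert report.by_equivalence[eq]["total"].count == count
            assert report.by_equivalence[eq]["total"].percent == pct(
                count, report.n_entries
            )
            assert report.by_equivalence[eq]["total"].percent == (
                expected.coverage_percents[eq]
            )


class TestTermCoverage:
    def test_verbatim_descriptions_give_full_coverage(self):
        table = MapTable([mapped("a b", "1"), mapped("c", "2")])
        cat = ConceptCatalog()
        cat.add(Description("1", "1", "a b"))
        cat.add(Description("2", "2", "c"))
        percent, updated = term_coverage(table, cat)
        assert percent == 100.00
        assert all(e.match_type == "direct_lexical" for e in updated)

    def test_printed_direct_match_counts_reproduce_percentage(self):
        entries = [
            mapped(f"e{i}", str(i), lang="english") for i in range(1140)
        ] + [mapped(f"t{i} x", str(9000 + i), lang="thai") for i in range(943)]
        cat = ConceptCatalog()
        for i in range(656):  # word-order variations of the first 656 terms
            cat.add(Description(str(i), str(i), f"E{i}".lower()))
        percent, updated = term_coverage(MapTable(entries), cat)
        assert percent == 31.49
        assert sum(1 for e in updated if e.match_type == "direct_lexical") == 656

    def test_designed_direct_fraction_recovered(self, study_run):
        study, _, _ = study_run
        percent, _ = term_coverage(study.gold_map, study.catalog)
        assert percent == pct(
            study.bookkeeping["direct_entry_target"], len(study.gold_map)
        )

    def test_no_thai_term_matches_latin_descriptions(self, study_run):
        study, _, _ = study_run
        _, updated = term_coverage(study.gold_map, study.catalog)
        assert not any(
            e.match_type == "direct_lexical"
            for e in updated
            if e.source_language == "thai"
        )


class TestUnmappedBreakdown:
    def test_printed_category_counts_reproduce_percentages(self):
        table = table_from_counts({"full": 1, "unmapped": 42})
        cats = (
            ["ambiguous"] * 23 + ["multiconcept"] * 10 + ["no_concept"] * 9
        )
        entries = [e for e in table if e.equivalence == "full"]
        for i, cat in enumerate(cats):
            entries.append(unmapped(f"u{i}", cat))
        out = unmapped_breakdown(MapTable(entries))
        assert (out["ambiguous"].count, out["ambiguous"].percent) == (23, 54.76)
        assert (out["multiconcept"].count, out["multiconcept"].percent) == (10, 23.81)
        assert (out["no_concept"].count, out["no_concept"].percent) == (9, 21.43)

    def test_single_category_is_total(self):
        out = unmapped_breakdown(MapTable([unmapped("x", "no_concept")]))
        assert out["no_concept"].percent == 100.00

    def test_missing_category_is_error(self):
        entry = MapEntry("x", "english", 1, None, "unmapped", "none")
        with pytest.raises(CoverageError):
            unmapped_breakdown(MapTable([entry]))

    def test_breakdown_counts_sum_to_unmapped(self, study_run):
        study, _, _ = study_run
        out = unmapped_breakdown(study.gold_map)
        assert sum(c.count for c in out.values()) == sum(
            1 for e in study.gold_map if e.equivalence == "unmapped"
        )


class TestRenderReport:
    def test_markdown_has_language_columns(self, study_run):
        study, _, _ = study_run
        text = render_report(full_report(study.gold_map, study.catalog), "markdown")
        assert "| Concept equivalency | English | Thai | Total |" in text

    def test_delimited_output_reparses_to_same_numbers(self, study_run):
        study, _, _ = study_run
        report = full_report(study.gold_map, study.catalog)
        lines = render_report(report, "delimited").splitlines()
        values = dict(
            line.split(",", 1) for line in lines if line and line.count(",") == 1
        )
        assert float(values["concept_coverage_full"]) == report.concept_coverage_full
        assert float(values["term_coverage_direct"]) == report.term_coverage_direct

    def test_unknown_format_is_error(self, study_run):
        study, _, _ = study_run
        with pytest.raises(CoverageError):
            render_report(concept_coverage(study.gold_map), "pdf")

    def test_optional_sections_omitted_without_catalog(self, study_run):
        study, _, _ = study_run
        report = concept_coverage(study.gold_map)
        assert "Term coverage" not in render_report(report, "text")
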