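"""Headline coverage statistics over a validated map table.

Concept coverage is the share of map entries whose source term is
representable by a concept (fully, or fully-plus-partially when broader /
narrower / inexact mappings are included).  Term coverage is the share of
entries whose source term lexically matches an existing description.  All
percentages use total map entries as the denominator and half-up rounding to
two decimals, matching how printed coverage tables are laid out.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

from ._text import pct
from .mapping import (
    EQUIVALENCES,
    UNMAPPED_CATEGORIES,
    ConceptCatalog,
    MapEntry,
    MapTable,
    detect_direct_lexical_match,
)

LANGUAGES = ("english", "thai")


class CoverageError(ValueError):
    pass


@dataclass
class Cell:
    count: int = 0
    percent: float = 0.0


@dataclass
class CoverageReport:
    n_entries: int = 0
    #: equivalence category -> language ("english"/"thai"/"total") -> Cell;
    #: includes a derived "partial" row (broader+narrower+inexact).
    by_equivalence: Dict[str, Dict[str, Cell]] = field(default_factory=dict)
    language_totals: Dict[str, Cell] = field(default_factory=dict)
    concept_coverage_full: float = 0.0
    concept_coverage_full_plus_partial: float = 0.0
    unmapped_percent: float = 0.0
    n_one_to_one_terms: int = 0
    n_one_to_many_terms: int = 0
    n_one_to_many_pairs: int = 0
    n_source_terms: int = 0
    n_unique_concepts: int = 0
    term_coverage_direct: Optional[float] = None
    #: direct matches as a share of English entries only (the alternative
    #: denominator; see the methods note).
    term_coverage_direct_english: Optional[float] = None
    n_direct_matches: int = 0
    unmapped_breakdown: Dict[str, Cell] = field(default_factory=dict)


def concept_coverage(table: MapTable) -> CoverageReport:
    """Equivalence-by-language counts and percentages plus entry accounting."""
    if len(table) == 0:
        raise CoverageError("cannot compute coverage of an empty map table")
    n = len(table)
    report = CoverageReport(n_entries=n)
    counts = {eq: {lang: 0 for lang in (*LANGUAGES, "total")} for eq in EQUIVALENCES}
    lang_totals = {lang: 0 for lang in (*LANGUAGES, "total")}
    for e in table:
        counts[e.equivalence][e.source_language] += 1
        counts[e.equivalence]["total"] += 1
        lang_totals[e.source_language] += 1
        lang_totals["total"] += 1
    for eq in EQUIVALENCES:
        report.by_equivalence[eq] = {
            lang: Cell(c, pct(c, n)) for lang, c in counts[eq].items()
        }
    partial = {
        lang: sum(counts[eq][lang] for eq in ("broader", "narrower", "inexact"))
        for lang in (*LANGUAGES, "total")
    }
    report.by_equivalence["partial"] = {
        lang: Cell(c, pct(c, n)) for lang, c in partial.items()
    }
    report.language_totals = {
        lang: Cell(c, pct(c, n)) for lang, c in lang_totals.items()
    }
    report.concept_coverage_full = pct(counts["full"]["total"], n)
    report.concept_coverage_full_plus_partial = pct(
        counts["full"]["total"] + partial["total"], n
    )
    report.unmapped_percent = pct(counts["unmapped"]["total"], n)
    acc = table.accounting()
    report.n_one_to_one_terms = acc["n_one_to_one_terms"]
    report.n_one_to_many_terms = acc["n_one_to_many_terms"]
    report.n_one_to_many_pairs = acc["n_one_to_many_pairs"]
    report.n_source_terms = acc["n_source_terms"]
    report.n_unique_concepts = acc["n_unique_concepts"]
    return report


def term_coverage(
    table: MapTable, catalog: ConceptCatalog
) -> Tuple[float, MapTable]:
    """Share of entries whose source term direct-lexically matches an active
    description.  Returns the percentage and a table with per-entry
    ``match_type`` updated (mapped entries become direct_lexical or
    contextual; unmapped entries stay 'none')."""
    updated: List[MapEntry] = []
    n_direct = 0
    for e in table:
        hit, _ = detect_direct_lexical_match(e.source_term, catalog)
        if e.equivalence == "unmapped":
            updated.append(e)
            continue
        if hit:
            n_direct += 1
        updated.append(replace(e, match_type="direct_lexical" if hit else "contextual"))
    return pct(n_direct, len(table)), MapTable(updated)


def unmapped_breakdown(table: MapTable) -> Dict[str, Cell]:
    """Counts and percentages of unmapped categories over the unmapped subset."""
    unmapped = [e for e in table if e.equivalence == "unmapped"]
    for e in unmapped:
        if e.unmapped_category is None:
            raise CoverageError(f"unmapped entry {e.source_term!r} lacks a category")
    total = len(unmapped)
    out = {}
    for cat in UNMAPPED_CATEGORIES:
        c = sum(1 for e in unmapped if e.unmapped_category == cat)
        out[cat] = Cell(c, pct(c, total) if total else 0.0)
    return out


def full_report(
    table: MapTable, catalog: Optional[ConceptCatalog] = None
) -> CoverageReport:
    """concept coverage + (optional) term coverage + unmapped breakdown."""
    report = concept_coverage(table)
    if catalog is not None:
        direct_pct, updated = term_coverage(table, catalog)
        report.term_coverage_direct = direct_pct
        report.n_direct_matches = sum(
            1 for e in updated if e.match_type == "direct_lexical"
        )
        n_english = sum(1 for e in table if e.source_language == "english")
        if n_english:
            report.term_coverage_direct_english = pct(
                report.n_direct_matches, n_english
            )
    if any(e.equivalence == "unmapped" and e.unmapped_category for e in table):
        report.unmapped_breakdown = unmapped_breakdown(table)
    return report


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_ROW_LABELS = {
    "full": "Fully mapped",
    "partial": "Partially mapped",
    "broader": "Broader",
    "narrower": "Narrower",
    "inexact": "Inexact",
    "unmapped": "Unmapped",
}
_ROW_ORDER = ("full", "partial", "broader", "narrower", "inexact", "unmapped")


def _equivalence_rows(report: CoverageReport) -> List[List[str]]:
    rows = []
    for eq in _ROW_ORDER:
        cells = report.by_equivalence[eq]
        rows.append(
            [_ROW_LABELS[eq]]
            + [
                f"{cells[lang].count} ({cells[lang].percent:.2f})"
                for lang in ("english", "thai", "total")
            ]
        )
    rows.append(
        ["Total"]
        + [
            f"{report.language_totals[lang].count} ({report.language_totals[lang].percent:.2f})"
            for lang in ("english", "thai", "total")
        ]
    )
    return rows


def render_report(report: CoverageReport, format: str = "text") -> str:
    """Render the coverage tables (concept coverage, accounting, term
    coverage, unmapped breakdown) as text, markdown, or delimited CSV."""
    if format not in ("text", "markdown", "delimited"):
        raise CoverageError(f"unknown report format {format!r}")
    header = ["Concept equivalency", "English", "Thai", "Total"]
    rows = _equivalence_rows(report)
    out = io.StringIO()
    if format == "delimited":
        print(",".join(header), file=out)
        for r in rows:
            print(",".join(str(c) for c in r), file=out)
        print(file=out)
        print(f"n_entries,{report.n_entries}", file=out)
        print(f"n_source_terms,{report.n_source_terms}", file=out)
        print(f"n_one_to_one_terms,{report.n_one_to_one_terms}", file=out)
        print(f"n_one_to_many_terms,{report.n_one_to_many_terms}", file=out)
        print(f"n_one_to_many_pairs,{report.n_one_to_many_pairs}", file=out)
        print(f"n_unique_concepts,{report.n_unique_concepts}", file=out)
        print(f"concept_coverage_full,{report.concept_coverage_full}", file=out)
        print(
            f"concept_coverage_full_plus_partial,{report.concept_coverage_full_plus_partial}",
            file=out,
        )
        if report.term_coverage_direct is not None:
            print(f"term_coverage_direct,{report.term_coverage_direct}", file=out)
        for cat, cell in report.unmapped_breakdown.items():
            print(f"unmapped_{cat},{cell.count},{cell.percent}", file=out)
        return out.getvalue()
    if format == "markdown":
        print("| " + " | ".join(header) + " |", file=out)
        print("|" + "---|" * len(header), file=out)
        for r in rows:
            print("| " + " | ".join(str(c) for c in r) + " |", file=out)
    else:
        widths = [
            max(len(str(r[i])) for r in [header, *rows]) for i in range(len(header))
        ]
        for r in [header, *rows]:
            print(
                "  ".join(str(c).ljust(w) for c, w in zip(r, widths)).rstrip(),
                file=out,
            )
    print(file=out)
    print(
        f"Entries: {report.n_entries} "
        f"({report.n_one_to_one_terms} one-to-one terms, "
        f"{report.n_one_to_many_terms} one-to-many terms -> "
        f"{report.n_one_to_many_pairs} pairs, "
        f"{report.by_equivalence['unmapped']['total'].count} unmapped); "
        f"{report.n_unique_concepts} unique concepts.",
        file=out,
    )
    print(
        f"Concept coverage: {report.concept_coverage_full:.2f}% full, "
        f"{report.concept_coverage_full_plus_partial:.2f}% full+partial.",
        file=out,
    )
    if report.term_coverage_direct is not None:
        print(
            f"Term coverage (direct lexical): {report.term_coverage_direct:.2f}% "
            f"of entries ({report.n_direct_matches} matches; "
            f"{report.term_coverage_direct_english:.2f}% of English entries).",
            file=out,
        )
    if report.unmapped_breakdown:
        parts = ", ".join(
            f"{cat} {cell.count} ({cell.percent:.2f}%)"
            for cat, cell in report.unmapped_breakdown.items()
        )
        print(f"Unmapped breakdown: {parts}.", file=out)
    return out.getvalue()
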