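"""Concept catalog (RF2-style) and the term -> concept map table.

The reference terminology distributes its content as tab-separated snapshot
files (Release Format 2).  The description snapshot is the only file this
pipeline needs: fully-specified-name rows define concepts (with a semantic
tag in trailing parentheses), synonym rows define the additional descriptions
used for direct lexical matching.

The map table mirrors a mapping-tool export: one row per source-term ->
concept pair, a relationship label per row, and explicit unmapped rows.  A
source term mapped to k concepts contributes k rows (one-to-many mapping);
equivalence is one of full / broader / narrower / inexact / unmapped.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from ._text import is_continuous_char, strip_punct

EQUIVALENCES = ("full", "broader", "narrower", "inexact", "unmapped")
UNMAPPED_CATEGORIES = ("ambiguous", "multiconcept", "no_concept")
MATCH_TYPES = ("direct_lexical", "contextual", "none")

#: bijection between export relationship labels and equivalence categories
RELATIONSHIP_TO_EQUIVALENCE = {
    "TARGET_EQUIVALENT": "full",
    "TARGET_BROADER": "broader",
    "TARGET_NARROWER": "narrower",
    "TARGET_INEXACT": "inexact",
}
EQUIVALENCE_TO_RELATIONSHIP = {v: k for k, v in RELATIONSHIP_TO_EQUIVALENCE.items()}

FSN_TYPE_ID = "900000000000003001"
SYNONYM_TYPE_ID = "900000000000013009"

_RF2_COLUMNS = (
    "id",
    "effectiveTime",
    "active",
    "moduleId",
    "conceptId",
    "languageCode",
    "typeId",
    "term",
    "caseSignificanceId",
)


class MappingError(ValueError):
    pass


@dataclass
class Concept:
    concept_id: str
    fsn: str
    semantic_tag: str = ""
    active: bool = True


@dataclass
class Description:
    description_id: str
    concept_id: str
    term: str
    language_code: str = "en"
    active: bool = True
    type_id: str = SYNONYM_TYPE_ID


def parse_semantic_tag(fsn: str) -> str:
    m = re.search(r"\(([^()]*)\)\s*$", fsn)
    return m.group(1).strip() if m else ""


def lexical_key(text: str) -> Tuple[str, ...]:
    """Order-insensitive bag-of-words key: case-folded, punctuation-stripped.

    "wound dressing" and "Dressing wound" share a key; paraphrases and
    abbreviations do not.  Symmetric and reflexive by construction.
    """
    words = strip_punct(text.casefold()).split()
    return tuple(sorted(words))


class ConceptCatalog:
    def __init__(
        self,
        concepts: Dict[str, Concept] | None = None,
        descriptions: List[Description] | None = None,
    ) -> None:
        self.concepts: Dict[str, Concept] = concepts or {}
        self.descriptions: List[Description] = descriptions or []
        self.n_inactive_dropped = 0
        self._lexical_index: Optional[Dict[Tuple[str, ...], str]] = None

    def add(self, description: Description, fsn: bool = False) -> None:
        self.descriptions.append(description)
        if fsn or description.type_id == FSN_TYPE_ID:
            description.type_id = FSN_TYPE_ID
            self.concepts.setdefault(
                description.concept_id,
                Concept(
                    description.concept_id,
                    description.term,
                    parse_semantic_tag(description.term),
                ),
            )
        self._lexical_index = None

    def active_descriptions(self) -> List[Description]:
        return [d for d in self.descriptions if d.active]

    def lexical_index(self) -> Dict[Tuple[str, ...], str]:
        if self._lexical_index is None:
            self._lexical_index = {}
            for d in self.active_descriptions():
                self._lexical_index.setdefault(lexical_key(d.term), d.description_id)
        return self._lexical_index


def load_concept_catalog(path, include_inactive: bool = False) -> ConceptCatalog:
    """Read an RF2-style description snapshot (TSV with header).

    Only active rows are retained by default; dropped rows are counted in
    ``catalog.n_inactive_dropped``.  A missing required column raises naming
    the column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, quoting=csv.QUOTE_NONE, keep_default_na=False)
    for col in ("id", "active", "conceptId", "term"):
        if col not in df.columns:
            raise MappingError(f"description snapshot is missing required column {col!r}")
    catalog = ConceptCatalog()
    for _, row in df.iterrows():
        active = row["active"] == "1"
        if not active and not include_inactive:
            catalog.n_inactive_dropped += 1
            continue
        desc = Description(
            description_id=row["id"],
            concept_id=row["conceptId"],
            term=row["term"],
            language_code=row.get("languageCode", "en"),
            active=active,
            type_id=row.get("typeId", SYNONYM_TYPE_ID),
        )
        catalog.add(desc)
    return catalog


def write_concept_catalog(catalog: ConceptCatalog, path) -> None:
    rows = []
    for d in catalog.descriptions:
        rows.append(
            {
                "id": d.description_id,
                "effectiveTime": "20240101",
                "active": "1" if d.active else "0",
                "moduleId": "0",
                "conceptId": d.concept_id,
                "languageCode": d.language_code,
                "typeId": d.type_id,
                "term": d.term,
                "caseSignificanceId": "900000000000448009",
            }
        )
    pd.DataFrame(rows, columns=_RF2_COLUMNS).to_csv(
        path, sep="\t", index=False, quoting=csv.QUOTE_NONE
    )


# ---------------------------------------------------------------------------
# map table
# ---------------------------------------------------------------------------


def classify_term_language(term: str) -> str:
    """"thai" if the term contains >=1 continuous-script character, else
    "english" (mixed-script terms count as thai)."""
    if not term:
        raise MappingError("cannot classify the language of an empty term")
    return "thai" if any(is_continuous_char(c) for c in term) else "english"


@dataclass
class MapEntry:
    source_term: str
    source_language: str
    n: int
    target_concept_id: Optional[str]
    equivalence: str
    match_type: str = "none"
    unmapped_category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.equivalence not in EQUIVALENCES:
            raise MappingError(f"unknown equivalence {self.equivalence!r}")
        if self.source_language not in ("thai", "english"):
            raise MappingError(f"unknown source language {self.source_language!r}")
        unmapped = self.equivalence == "unmapped"
        if unmapped != (self.target_concept_id is None) or unmapped != (
            self.match_type == "none"
        ):
            raise MappingError(
                f"inconsistent entry for {self.source_term!r}: unmapped entries "
                "(and only those) have no target and match_type 'none'"
            )
        if self.unmapped_category is not None and not unmapped:
            raise MappingError("unmapped_category set on a mapped entry")
        if self.unmapped_category is not None and self.unmapped_category not in UNMAPPED_CATEGORIES:
            raise MappingError(f"unknown unmapped category {self.unmapped_category!r}")
        if self.match_type not in MATCH_TYPES:
            raise MappingError(f"unknown match type {self.match_type!r}")


class MapTable:
    def __init__(self, entries: Sequence[MapEntry] = ()) -> None:
        self.entries: List[MapEntry] = list(entries)
        self.validate()

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_source(self) -> Dict[str, List[MapEntry]]:
        idx: Dict[str, List[MapEntry]] = {}
        for e in self.entries:
            idx.setdefault(e.source_term, []).append(e)
        return idx

    def validate(self) -> None:
        """Check the entry-accounting invariants.

        A source term is never both mapped and unmapped, mapped targets of a
        term are distinct, and |entries| = one-to-one terms + one-to-many
        pairs + unmapped terms.
        """
        for term, entries in self.by_source().items():
            kinds = {e.equivalence == "unmapped" for e in entries}
            if len(kinds) > 1:
                raise MappingError(f"term {term!r} is both mapped and unmapped")
            targets = [e.target_concept_id for e in entries if e.target_concept_id]
            if len(targets) != len(set(targets)):
                raise MappingError(f"term {term!r} maps twice to one concept")
            if True in kinds and len(entries) > 1:
                raise MappingError(f"term {term!r} has multiple unmapped rows")
        acc = self.accounting()
        assert acc["n_entries"] == (
            acc["n_one_to_one_terms"] + acc["n_one_to_many_pairs"] + acc["n_unmapped_terms"]
        )

    def accounting(self) -> Dict[str, int]:
        by_src = self.by_source()
        mapped_groups = [
            v for v in by_src.values() if v[0].equivalence != "unmapped"
        ]
        one_to_many = [v for v in mapped_groups if len(v) > 1]
        return {
            "n_entries": len(self.entries),
            "n_source_terms": len(by_src),
            "n_one_to_one_terms": sum(1 for v in mapped_groups if len(v) == 1),
            "n_one_to_many_terms": len(one_to_many),
            "n_one_to_many_pairs": sum(len(v) for v in one_to_many),
            "n_unmapped_terms": sum(
                1 for v in by_src.values() if v[0].equivalence == "unmapped"
            ),
            "n_unique_concepts": len(
                {e.target_concept_id for e in self.entries if e.target_concept_id}
            ),
        }


_MAP_COLUMNS = (
    "source_term",
    "source_language",
    "n",
    "target_concept_id",
    "relationship",
    "match_type",
    "unmapped_category",
)


def write_map_table(table: MapTable, path) -> None:
    rows = []
    for e in table:
        rows.append(
            {
                "source_term": e.source_term,
                "source_language": e.source_language,
                "n": e.n,
                "target_concept_id": e.target_concept_id or "",
                "relationship": (
                    "UNMAPPED"
                    if e.equivalence == "unmapped"
                    else EQUIVALENCE_TO_RELATIONSHIP[e.equivalence]
                ),
                "match_type": e.match_type,
                "unmapped_category": e.unmapped_category or "",
            }
        )
    pd.DataFrame(rows, columns=_MAP_COLUMNS).to_csv(path, index=False)


def load_map_table(path) -> MapTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _MAP_COLUMNS:
        if col not in df.columns:
            raise MappingError(f"map table is missing required column {col!r}")
    entries = []
    for _, row in df.iterrows():
        rel = row["relationship"]
        if rel == "UNMAPPED":
            equivalence = "unmapped"
        elif rel in RELATIONSHIP_TO_EQUIVALENCE:
            equivalence = RELATIONSHIP_TO_EQUIVALENCE[rel]
        else:
            raise MappingError(f"unknown relationship value {rel!r}")
        entries.append(
            MapEntry(
                source_term=row["source_term"],
                source_language=row["source_language"],
                n=int(row["n"]),
                target_concept_id=row["target_concept_id"] or None,
                equivalence=equivalence,
                match_type=row["match_type"],
                unmapped_category=row["unmapped_category"] or None,
            )
        )
    return MapTable(entries)


def detect_direct_lexical_match(
    term: str, catalog: ConceptCatalog
) -> Tuple[bool, Optional[str]]:
    """Does ``term`` lexically match any active description?

    Match means equal normalized word multisets (case-insensitive,
    punctuation-stripped, order-insensitive): simple variations of writing
    count, paraphrases and abbreviation expansions do not.
    """
    desc_id = catalog.lexical_index().get(lexical_key(term))
    return (desc_id is not None), desc_id
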