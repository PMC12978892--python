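"""Clinical document collections and corpus-level descriptive statistics.

A corpus is an ordered collection of outpatient notes, each carrying a
department code (FM = family medicine, ER = emergency, IM = internal
medicine) and two free-text sections: the chief complaint and the present
illness.  On disk a corpus is UTF-8 JSON-lines, one document per line —
streamable and diff-friendly.

Word-level statistics are computed over *tokens* produced by the dictionary
segmenter, not over whitespace splits: for continuous-script text the notion
of "word" only exists after segmentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from ._text import is_continuous_char, pct

DEPARTMENTS = ("FM", "ER", "IM")


class CorpusError(ValueError):
    """Raised for malformed corpus files or inconsistent corpora."""


@dataclass(frozen=True)
class Document:
    doc_id: str
    patient_id: str
    department: str
    chief_complaint: str = ""
    present_illness: str = ""

    def __post_init__(self) -> None:
        if self.department not in DEPARTMENTS:
            raise CorpusError(
                f"unknown department code {self.department!r} for document {self.doc_id!r}"
            )

    @property
    def sections(self) -> Tuple[str, str]:
        return (self.chief_complaint, self.present_illness)

    @property
    def is_empty(self) -> bool:
        return not self.chief_complaint.strip() and not self.present_illness.strip()

    def with_sections(self, chief_complaint: str, present_illness: str) -> "Document":
        return replace(
            self, chief_complaint=chief_complaint, present_illness=present_illness
        )


@dataclass
class Corpus:
    documents: List[Document] = field(default_factory=list)
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise CorpusError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.documents == other.documents

    def patient_ids(self) -> List[str]:
        return [d.patient_id for d in self.documents]


_FIELDS = ("doc_id", "patient_id", "department", "chief_complaint", "present_illness")


def read_corpus(path) -> Corpus:
    """Read a JSON-lines corpus.

    Records in which both text sections are empty are excluded; their count is
    recorded in ``corpus.metadata["n_excluded"]``.  Malformed lines raise
    :class:`CorpusError` naming the line number.
    """
    documents: List[Document] = []
    n_excluded = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"line {lineno}: invalid JSON record ({exc.msg})") from exc
            missing = [f for f in _FIELDS if f not in record]
            if missing:
                raise CorpusError(f"line {lineno}: missing fields {missing}")
            try:
                doc = Document(**{f: record[f] for f in _FIELDS})
            except CorpusError as exc:
                raise CorpusError(f"line {lineno}: {exc}") from exc
            if doc.is_empty:
                n_excluded += 1
                continue
            documents.append(doc)
    corpus = Corpus(documents)
    corpus.metadata["n_excluded"] = n_excluded
    return corpus


def write_corpus(corpus: Corpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus:
            record = {f: getattr(doc, f) for f in _FIELDS}
            fh.write(json.dumps(record, ensure_ascii=False, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------


@dataclass
class DeptStats:
    """One column of the corpus-characteristics table."""

    n_patients: int = 0
    n_documents: int = 0
    docs_per_patient_median: float = 0.0
    docs_per_patient_iqr: Tuple[float, float] = (0.0, 0.0)
    unique_words: int = 0
    unique_continuous_words: int = 0
    unique_continuous_pct: float = 0.0
    total_words: int = 0
    total_continuous_words: int = 0
    total_continuous_pct: float = 0.0
    words_per_doc_median: float = 0.0
    words_per_doc_iqr: Tuple[float, float] = (0.0, 0.0)


@dataclass
class CorpusStats:
    per_department: Dict[str, DeptStats]
    overall: DeptStats
    #: patients counted once per department they visited (the overall
    #: n_patients deduplicates across departments; the table stores both).
    n_patients_department_sum: int = 0


def is_continuous_word(surface: str) -> bool:
    """A word counts as continuous-script if it contains >=1 such character."""
    return any(is_continuous_char(c) for c in surface)


def _median_iqr(values: Sequence[float]) -> Tuple[float, Tuple[float, float]]:
    if not values:
        return 0.0, (0.0, 0.0)
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    return float(med), (float(q1), float(q3))


def _dept_stats(
    docs: Sequence[Document], token_lists: Sequence[Sequence[str]]
) -> DeptStats:
    stats = DeptStats()
    stats.n_documents = len(docs)
    stats.n_patients = len({d.patient_id for d in docs})
    per_patient: Dict[str, int] = {}
    for d in docs:
        per_patient[d.patient_id] = per_patient.get(d.patient_id, 0) + 1
    stats.docs_per_patient_median, stats.docs_per_patient_iqr = _median_iqr(
        list(per_patient.values())
    )
    uniq: set = set()
    uniq_cont: set = set()
    total = 0
    total_cont = 0
    words_per_doc: List[int] = []
    for tokens in token_lists:
        words_per_doc.append(len(tokens))
        for t in tokens:
            total += 1
            uniq.add(t)
            if is_continuous_word(t):
                total_cont += 1
                uniq_cont.add(t)
    stats.unique_words = len(uniq)
    stats.unique_continuous_words = len(uniq_cont)
    stats.total_words = total
    stats.total_continuous_words = total_cont
    if stats.unique_words:
        stats.unique_continuous_pct = pct(len(uniq_cont), len(uniq))
    if total:
        stats.total_continuous_pct = pct(total_cont, total)
    stats.words_per_doc_median, stats.words_per_doc_iqr = _median_iqr(words_per_doc)
    return stats


def compute_corpus_stats(
    corpus: Corpus, tokens_per_doc: Sequence[Sequence[str]]
) -> CorpusStats:
    """Corpus characteristics per department and overall.

    ``tokens_per_doc`` is aligned with ``corpus.documents``; each element is
    the flat list of token surfaces of that document (post-segmentation).
    """
    if len(tokens_per_doc) != len(corpus):
        raise CorpusError(
            f"tokens_per_doc has {len(tokens_per_doc)} entries for "
            f"{len(corpus)} documents"
        )
    by_dept: Dict[str, List[int]] = {d: [] for d in DEPARTMENTS}
    for i, doc in enumerate(corpus):
        by_dept[doc.department].append(i)
    per_department = {
        dept: _dept_stats(
            [corpus.documents[i] for i in idx], [tokens_per_doc[i] for i in idx]
        )
        for dept, idx in by_dept.items()
    }
    overall = _dept_stats(list(corpus.documents), list(tokens_per_doc))
    dept_sum = sum(s.n_patients for s in per_department.values())
    return CorpusStats(
        per_department=per_department,
        overall=overall,
        n_patients_department_sum=dept_sum,
    )


def word_share(parts: Mapping[str, int], wholes: Mapping[str, int], ndigits: int = 2) -> float:
    """Overall percentage of a word class from per-department counts.

    Sums the per-department numerators and denominators and applies the
    table rounding rule — e.g. per-department continuous-script word counts
    against per-department word totals give the overall continuous-script
    share.
    """
    return pct(sum(parts.values()), sum(wholes.values()), ndigits)
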