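"""Normalization, per-patient duplicate-sentence elimination, spell-check.

Fixed pipeline order (capitals must survive for abbreviation harvesting, and
spelling must be fixed before dictionary segmentation):

    abbreviation harvest -> normalize -> dedup -> spell-check -> tokenize

Normalization lowercases Latin letters, maps punctuation to spaces, collapses
space runs, and applies an ordered list of pluggable script-specific rules
(identity by default; real-language tone-mark/vowel reordering rules can be
supplied as patterns).  Newlines are preserved: they are the sentence
delimiter used by duplicate elimination.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

from ._text import is_latin_char, strip_punct
from .corpus import Corpus, Document
from .lexicon import Lexicon, spell_correct

logger = logging.getLogger(__name__)


@dataclass
class NormalizationRule:
    """A pure pattern -> replacement rewrite, applied in declared order.

    Rules are expected to be idempotent (a rule that reorders a misplaced
    diacritic pair must not fire again on canonical text).
    """

    name: str
    pattern: str
    replacement: str
    enabled: bool = True

    def apply(self, text: str) -> str:
        if not self.enabled:
            return text
        return re.sub(self.pattern, self.replacement, text)


@dataclass
class PreprocessReport:
    chars_in: int = 0
    chars_out: int = 0
    duplicates_removed: int = 0
    corrections_applied: int = 0

    @property
    def removal_fraction(self) -> float:
        if self.chars_in == 0:
            return 0.0
        return (self.chars_in - self.chars_out) / self.chars_in

    def merge(self, other: "PreprocessReport") -> "PreprocessReport":
        return PreprocessReport(
            chars_in=self.chars_in or other.chars_in,
            chars_out=other.chars_out or self.chars_out,
            duplicates_removed=self.duplicates_removed + other.duplicates_removed,
            corrections_applied=self.corrections_applied + other.corrections_applied,
        )


def normalize_text(text: str, rules: Sequence[NormalizationRule] = ()) -> str:
    """Case-fold, punctuation->space, collapse spaces; then apply ``rules``.

    Idempotent; never produces leading/trailing whitespace.  Newlines survive
    as line separators (empty lines are dropped).
    """
    lines = []
    for line in text.split("\n"):
        line = strip_punct(line.lower())
        line = " ".join(line.split())
        for rule in rules:
            line = rule.apply(line)
        line = " ".join(line.split())
        if line:
            lines.append(line)
    return "\n".join(lines)


def _map_sections(corpus: Corpus, fn) -> Corpus:
    docs = [doc.with_sections(fn(doc.chief_complaint), fn(doc.present_illness)) for doc in corpus]
    out = Corpus(docs)
    out.metadata.update(corpus.metadata)
    return out


def _total_chars(corpus: Corpus) -> int:
    return sum(len(s) for doc in corpus for s in doc.sections)


def normalize_corpus(
    corpus: Corpus, rules: Sequence[NormalizationRule] = ()
) -> Tuple[Corpus, PreprocessReport]:
    report = PreprocessReport(chars_in=_total_chars(corpus))
    out = _map_sections(corpus, lambda s: normalize_text(s, rules))
    report.chars_out = _total_chars(out)
    return out, report


def dedup_sentences(
    corpus: Corpus, granularity: str = "sentence"
) -> Tuple[Corpus, PreprocessReport]:
    """Remove sentences repeated from a patient's earlier documents.

    Sentences are newline-delimited (documents are assumed normalized).  The
    first occurrence is always kept; scope is per patient, in corpus order.
    ``granularity="entry"`` instead drops whole documents whose full text was
    already seen for the patient.
    """
    if granularity not in ("sentence", "entry"):
        raise ValueError(f"unknown dedup granularity {granularity!r}")
    report = PreprocessReport(chars_in=_total_chars(corpus))
    seen: Dict[str, Set[str]] = {}
    docs: List[Document] = []
    for doc in corpus:
        patient_seen = seen.setdefault(doc.patient_id, set())
        if granularity == "entry":
            key = "\n".join(doc.sections).strip()
            if key and key in patient_seen:
                report.duplicates_removed += 1
                docs.append(doc.with_sections("", ""))
                continue
            new_sections = doc.sections
            if key:
                patient_seen.add(key)
        else:
            new_sections = []
            added: List[str] = []
            for section in doc.sections:
                kept = []
                for sentence in section.split("\n"):
                    s = sentence.strip()
                    if not s:
                        continue
                    if s in patient_seen:
                        report.duplicates_removed += 1
                    else:
                        kept.append(s)
                        added.append(s)
                new_sections.append("\n".join(kept))
            # sentences become "seen" only after the whole document, so a
            # within-document repeat is kept: only prior *visits* dedup.
            patient_seen.update(added)
        docs.append(doc.with_sections(new_sections[0], new_sections[1]))
    out = Corpus(docs)
    out.metadata.update(corpus.metadata)
    report.chars_out = _total_chars(out)
    return out, report


#: spell-check only plain-Latin tokens at least this long; distance-1
#: "correction" of very short tokens and abbreviations is unsafe.
SPELLCHECK_MIN_LEN = 4


def apply_spell_check(
    corpus: Corpus, lexicon: Lexicon, max_edit: int = 1
) -> Tuple[Corpus, PreprocessReport]:
    """Run dictionary spell correction over every eligible token.

    Eligible tokens are space-delimited, purely Latin, and at least
    :data:`SPELLCHECK_MIN_LEN` characters; continuous-script runs are never
    touched.  Corrections are counted in the report.
    """
    report = PreprocessReport(chars_in=_total_chars(corpus))
    cache: Dict[str, str] = {}

    def fix_token(tok: str) -> str:
        if len(tok) < SPELLCHECK_MIN_LEN or not all(is_latin_char(c) for c in tok):
            return tok
        if tok not in cache:
            # the corpus is already case-normalized, so a correction drawn
            # from a cased dictionary surface is folded back to lowercase
            cache[tok] = spell_correct(tok, lexicon, max_edit).casefold()
        if cache[tok] != tok:
            report.corrections_applied += 1
        return cache[tok]

    def fix_section(section: str) -> str:
        lines = []
        for line in section.split("\n"):
            lines.append(" ".join(fix_token(t) for t in line.split(" ") if t))
        return "\n".join(lines)

    out = _map_sections(corpus, fix_section)
    report.chars_out = _total_chars(out)
    return out, report


def run_preprocess(
    corpus: Corpus,
    lexicon: Lexicon,
    rules: Sequence[NormalizationRule] = (),
    dedup_granularity: str = "sentence",
    max_edit: int = 1,
) -> Tuple[Corpus, PreprocessReport]:
    """normalize -> dedup -> spell-check, with a combined report.

    ``chars_in``/``chars_out`` span the whole pipeline, so
    ``removal_fraction`` is the total character share removed by cleaning —
    the number reported alongside the corpus characteristics.
    """
    chars_in = _total_chars(corpus)
    corpus, _ = normalize_corpus(corpus, rules)
    corpus, rep_dedup = dedup_sentences(corpus, dedup_granularity)
    corpus, rep_spell = apply_spell_check(corpus, lexicon, max_edit)
    report = PreprocessReport(
        chars_in=chars_in,
        chars_out=_total_chars(corpus),
        duplicates_removed=rep_dedup.duplicates_removed,
        corrections_applied=rep_spell.corrections_applied,
    )
    logger.info(
        "preprocess: %.2f%% of characters removed, %d duplicate sentences, %d corrections",
        100 * report.removal_fraction,
        report.duplicates_removed,
        report.corrections_applied,
    )
    return corpus, report
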