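"""The custom dictionary D: construction, abbreviation harvesting, spell lookup.

The dictionary unions five source classes (general-English word list, local
continuous-script word list, reference-terminology descriptions, drug
terminology, reviewed abbreviations) plus ad-hoc custom entries.  It backs
both the maximum-matching segmenter and pre-tokenization spell correction.

Match keys case-fold Latin letters; continuous-script entries are kept
verbatim (the script has no case).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from ._text import is_latin_char, is_punct_char
from .corpus import Corpus

logger = logging.getLogger(__name__)

SOURCES = (
    "wordnet_en",
    "wordnet_local",
    "concept_descriptions",
    "drug_db",
    "abbreviations",
    "custom",
)


class LexiconError(ValueError):
    pass


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    source: str = "custom"
    is_abbreviation: bool = False

    def __post_init__(self) -> None:
        if not self.surface or self.surface != self.surface.strip():
            raise LexiconError(f"bad lexicon surface {self.surface!r}")
        if self.source not in SOURCES:
            raise LexiconError(f"unknown lexicon source {self.source!r}")


def match_key(surface: str) -> str:
    return surface.casefold()


class Lexicon:
    """Set of entries with a longest-match index.

    The index stores, per first character of the match key, the distinct
    entry lengths in descending order, so the segmenter can probe only
    lengths that exist.
    """

    def __init__(self, entries: Iterable[LexiconEntry] = ()) -> None:
        self._entries: Dict[str, LexiconEntry] = {}
        self._lengths: Dict[str, List[int]] = {}
        self.max_entry_length = 0
        for e in entries:
            self.add(e)

    def add(self, entry: LexiconEntry) -> bool:
        """Add an entry; first source wins on duplicate keys. Returns True if new."""
        key = match_key(entry.surface)
        if key in self._entries:
            return False
        self._entries[key] = entry
        self._lengths.setdefault(key[0], [])
        lens = self._lengths[key[0]]
        if len(key) not in lens:
            lens.append(len(key))
            lens.sort(reverse=True)
        self.max_entry_length = max(self.max_entry_length, len(key))
        return True

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, surface: str) -> bool:
        return match_key(surface) in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def get(self, surface: str) -> Optional[LexiconEntry]:
        return self._entries.get(match_key(surface))

    def lengths_starting_with(self, ch: str) -> Sequence[int]:
        return self._lengths.get(ch.casefold(), ())

    def has_key(self, key: str) -> bool:
        return key in self._entries

    def surfaces(self) -> List[str]:
        return [e.surface for e in self._entries.values()]


def build_lexicon(
    source_files: Sequence[Tuple[object, str]],
    extra_entries: Iterable[LexiconEntry] = (),
) -> Lexicon:
    """Union word-list files (one term per line, ``#`` comments) into a lexicon.

    ``source_files`` is a sequence of ``(path, source_tag)``.  Duplicates
    across sources keep the first source tag.  An empty union is an error:
    with no dictionary the segmenter would degenerate to emitting characters.
    """
    lexicon = Lexicon()
    for path, tag in source_files:
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                term = line.split("#", 1)[0].strip()
                if not term:
                    continue
                lexicon.add(
                    LexiconEntry(term, source=tag, is_abbreviation=tag == "abbreviations")
                )
    for entry in extra_entries:
        lexicon.add(entry)
    if len(lexicon) == 0:
        raise LexiconError("empty lexicon: no entries in any source")
    return lexicon


def write_word_list(surfaces: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in surfaces:
            fh.write(s + "\n")


# ---------------------------------------------------------------------------
# abbreviation harvesting
# ---------------------------------------------------------------------------


@dataclass
class AbbreviationCandidate:
    surface: str
    n_capitals: int
    corpus_frequency: int
    accepted: bool = False


def _raw_tokens(text: str) -> Iterable[str]:
    """Whitespace/punctuation-delimited tokens of raw (unnormalized) text."""
    buf: List[str] = []
    for ch in text:
        if ch.isspace() or is_punct_char(ch):
            if buf:
                yield "".join(buf)
                buf = []
        else:
            buf.append(ch)
    if buf:
        yield "".join(buf)


def count_capitals(token: str) -> int:
    return sum(1 for c in token if is_latin_char(c) and c.isupper())


def harvest_abbreviations(
    corpus: Corpus,
    min_capitals: int = 2,
    min_frequency_exclusive: int = 100,
) -> List[AbbreviationCandidate]:
    """Abbreviation candidates: >= ``min_capitals`` capital Latin letters and a
    corpus frequency strictly above ``min_frequency_exclusive``.

    Must run on raw text, before case normalization.  Candidates are sorted by
    frequency descending (surface as tie-break); acceptance is an external
    expert decision and is left unset.
    """
    freq: Counter = Counter()
    for doc in corpus:
        for section in doc.sections:
            freq.update(_raw_tokens(section))
    out = [
        AbbreviationCandidate(tok, count_capitals(tok), n)
        for tok, n in freq.items()
        if count_capitals(tok) >= min_capitals and n > min_frequency_exclusive
    ]
    out.sort(key=lambda c: (-c.corpus_frequency, c.surface))
    return out


def write_abbreviation_sheet(candidates: Sequence[AbbreviationCandidate], path) -> None:
    pd.DataFrame(
        {
            "surface": [c.surface for c in candidates],
            "frequency": [c.corpus_frequency for c in candidates],
            "accepted": ["yes" if c.accepted else "no" for c in candidates],
            "expansion": ["" for _ in candidates],
        }
    ).to_csv(path, index=False)


def read_abbreviation_review(path) -> Dict[str, bool]:
    """Read a reviewed abbreviation sheet back as surface -> accepted."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return {
        row["surface"]: row["accepted"].strip().lower() in ("yes", "y", "true", "1")
        for _, row in df.iterrows()
    }


# ---------------------------------------------------------------------------
# spell correction
# ---------------------------------------------------------------------------


def levenshtein_leq(a: str, b: str, k: int) -> bool:
    """True iff edit distance(a, b) <= k (banded dynamic programme)."""
    if abs(len(a) - len(b)) > k:
        return False
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        best = i
        for j, cb in enumerate(b, start=1):
            cost = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            cur.append(cost)
            best = min(best, cost)
        if best > k:
            return False
        prev = cur
    return prev[-1] <= k


def spell_neighbors(token: str, lexicon: Lexicon, max_edit: int = 1) -> List[str]:
    """Lexicon surfaces within edit distance <= max_edit of ``token``.

    Only Latin-script entries are considered; the key space is case-folded.
    """
    key = match_key(token)
    out = []
    for entry in lexicon:
        ekey = match_key(entry.surface)
        if " " in ekey:
            continue
        if not all(is_latin_char(c) for c in ekey):
            continue
        if levenshtein_leq(key, ekey, max_edit):
            out.append(entry.surface)
    return out


def spell_correct(token: str, lexicon: Lexicon, max_edit: int = 1) -> str:
    """Dictionary spell correction of one space-delimited token.

    In-lexicon tokens pass through.  Otherwise the unique lexicon entry
    within ``max_edit`` edits is returned if exactly one exists; ambiguity or
    no neighbor leaves the token unchanged.
    """
    if token in lexicon:
        return token
    neighbors = spell_neighbors(token, lexicon, max_edit)
    if len(neighbors) == 1:
        logger.debug("spell-corrected %r -> %r", token, neighbors[0])
        return neighbors[0]
    if len(neighbors) > 1:
        logger.debug("ambiguous correction for %r: %s", token, neighbors)
    return token
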