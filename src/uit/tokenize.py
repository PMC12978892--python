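"""Maximum-matching segmentation of mixed-script clinical text.

Continuous-script languages (Thai here) write words without separators, so
"ischemic heart disease" style compounds arrive as one unbroken character
run.  The segmenter scans left to right; at each position it takes the
longest dictionary entry that matches exactly and advances past it.  When no
entry matches, the fallback policy emits an unknown token — by default the
maximal run of unmatched same-script characters, so that downstream N-grams
stay meaningful.

Whitespace is always a token boundary (consumed, never emitted).  A script
change (continuous <-> Latin <-> digit) is treated like whitespace by
default; multiword Latin dictionary entries may span internal spaces when
explicitly allowed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

from ._text import char_class, classify_script  # re-exported: spec op lives here
from .corpus import Corpus, Document
from .lexicon import Lexicon

__all__ = [
    "Token",
    "TokenizerConfig",
    "max_match_tokenize",
    "classify_script",
    "tokenize_corpus",
]


class TokenizeError(ValueError):
    pass


@dataclass(frozen=True)
class Token:
    surface: str
    start: int  # 0-based character offset into the source text
    end: int  # half-open
    script: str
    in_dictionary: bool


@dataclass(frozen=True)
class TokenizerConfig:
    #: "merge_run" merges a maximal unmatched same-script run into one
    #: unknown token; "single_char" emits unknown characters one by one.
    unknown_fallback: str = "merge_run"
    whitespace_is_boundary: bool = True  # fixed; recorded for the run log
    #: allow dictionary entries containing internal spaces (multiword
    #: English jargon) to match across whitespace.
    allow_multiword_entries: bool = False
    #: treat a change of script class like whitespace.
    script_change_is_boundary: bool = True

    def __post_init__(self) -> None:
        if self.unknown_fallback not in ("merge_run", "single_char"):
            raise TokenizeError(f"unknown fallback policy {self.unknown_fallback!r}")
        if not self.whitespace_is_boundary:
            raise TokenizeError("whitespace_is_boundary is fixed true")


DEFAULT_CONFIG = TokenizerConfig()


def _valid_span(text: str, start: int, length: int, config: TokenizerConfig) -> bool:
    """May a dictionary entry occupy text[start:start+length]?"""
    span = text[start : start + length]
    if span[0].isspace() or span[-1].isspace():
        return False
    if not config.allow_multiword_entries and any(c.isspace() for c in span):
        return False
    if config.script_change_is_boundary:
        base = char_class(span[0])
        for c in span:
            cls = char_class(c)
            if cls == "space":
                continue
            if cls != base:
                return False
    return True


def _longest_match(
    text: str, pos: int, lexicon: Lexicon, config: TokenizerConfig
) -> int:
    """Length of the longest lexicon entry matching at ``pos`` (0 if none)."""
    limit = min(lexicon.max_entry_length, len(text) - pos)
    for length in lexicon.lengths_starting_with(text[pos]):
        if length > limit:
            continue
        if not _valid_span(text, pos, length, config):
            continue
        if lexicon.has_key(text[pos : pos + length].casefold()):
            return length
    return 0


def max_match_tokenize(
    text: str, lexicon: Lexicon, config: TokenizerConfig = DEFAULT_CONFIG
) -> List[Token]:
    """Greedy longest-match segmentation of ``text`` against ``lexicon``.

    The concatenation of token surfaces plus skipped whitespace reconstructs
    the input exactly; every character lies in exactly one token or is
    whitespace.
    """
    if len(lexicon) == 0:
        raise TokenizeError("cannot tokenize with an empty lexicon")
    tokens: List[Token] = []
    n = len(text)
    j = 0
    while j < n:
        if text[j].isspace():
            j += 1
            continue
        length = _longest_match(text, j, lexicon, config)
        if length:
            surface = text[j : j + length]
            tokens.append(Token(surface, j, j + length, classify_script(surface), True))
            j += length
            continue
        if config.unknown_fallback == "single_char":
            tokens.append(Token(text[j], j, j + 1, classify_script(text[j]), False))
            j += 1
            continue
        # merge_run: extend over unmatched characters of the same script
        # class until whitespace, a script change, or a position where some
        # dictionary entry begins to match.
        base = char_class(text[j])
        k = j + 1
        while (
            k < n
            and not text[k].isspace()
            and (not config.script_change_is_boundary or char_class(text[k]) == base)
            and _longest_match(text, k, lexicon, config) == 0
        ):
            k += 1
        surface = text[j:k]
        tokens.append(Token(surface, j, k, classify_script(surface), False))
        j = k
    return tokens


@dataclass
class DocumentTokens:
    """Tokens of one document, kept per section so that candidate N-grams
    never span the chief-complaint / present-illness boundary."""

    doc_id: str
    sections: List[List[Token]]

    def flat_surfaces(self) -> List[str]:
        return [t.surface for sec in self.sections for t in sec]

    def section_surfaces(self) -> List[List[str]]:
        return [[t.surface for t in sec] for sec in self.sections]


def tokenize_corpus(
    corpus: Corpus, lexicon: Lexicon, config: TokenizerConfig = DEFAULT_CONFIG
) -> List[DocumentTokens]:
    """Tokenize every document; sentence lines are separate sequences joined
    per section (newlines are whitespace to the segmenter)."""
    return [
        DocumentTokens(
            doc.doc_id,
            [max_match_tokenize(section, lexicon, config) for section in doc.sections],
        )
        for doc in corpus
    ]
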