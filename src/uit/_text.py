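"""Shared character/script helpers and print-style rounding.

"Continuous script" means a writing system without inter-word spaces (Thai
here).  The tokenizer and the synthetic language both rely on a configurable
set of code-point ranges to recognise such characters; the defaults cover the
Thai block and the Basic Multilingual Plane private-use area used by the
synthetic script.
"""

from __future__ import annotations

import unicodedata
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache
from typing import Iterable, Tuple

#: (lo, hi) inclusive code-point ranges treated as continuous script.
CONTINUOUS_RANGES: Tuple[Tuple[int, int], ...] = (
    (0x0E00, 0x0E7F),  # Thai
    (0xE000, 0xF8FF),  # private use area (synthetic continuous script)
)


def is_continuous_char(ch: str) -> bool:
    cp = ord(ch)
    return any(lo <= cp <= hi for lo, hi in CONTINUOUS_RANGES)


def is_latin_char(ch: str) -> bool:
    return ("a" <= ch <= "z") or ("A" <= ch <= "Z")


@lru_cache(maxsize=4096)
def is_punct_char(ch: str) -> bool:
    return unicodedata.category(ch).startswith("P")


def char_class(ch: str) -> str:
    """Coarse class of a single character: continuous/latin/digit/space/other."""
    if ch.isspace():
        return "space"
    if is_continuous_char(ch):
        return "continuous"
    if is_latin_char(ch):
        return "latin"
    if ch.isdigit():
        return "digit"
    return "other"


def classify_script(surface: str) -> str:
    """Script class of a token surface.

    continuous: >=1 continuous-script character and no Latin letter;
    latin: only Latin letters; digit: only digits; mixed: both continuous
    and Latin; other: anything else.  Raises on empty input.
    """
    if not surface:
        raise ValueError("cannot classify an empty surface")
    has_cont = any(is_continuous_char(c) for c in surface)
    has_latin = any(is_latin_char(c) for c in surface)
    if has_cont and has_latin:
        return "mixed"
    if has_cont:
        return "continuous"
    if has_latin:
        return "latin" if all(is_latin_char(c) for c in surface) else "other"
    if all(c.isdigit() for c in surface):
        return "digit"
    return "other"


def strip_punct(text: str) -> str:
    """Replace every Unicode punctuation character by a space."""
    return "".join(" " if is_punct_char(c) else c for c in text)


def round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Half-up rounded percentage, computed exactly for integer inputs.

    This is the rounding rule used for every printed-table percentage.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(1).scaleb(-ndigits)
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def join_surfaces(surfaces: Iterable[str]) -> str:
    """Display form of a token sequence.

    Adjacent continuous-script tokens are joined without a space (that is how
    they appear in running text); anything else is space-separated.
    """
    out: list[str] = []
    prev_cont = False
    for s in surfaces:
        cont = bool(s) and all(is_continuous_char(c) for c in s)
        if out and not (prev_cont and cont):
            out.append(" ")
        out.append(s)
        prev_cont = cont
    return "".join(out)
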