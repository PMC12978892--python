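"""Candidate-term generation and interface-term selection.

Candidate terms are N-grams (N = 1..5) of segmenter tokens.  Syntactically
irrelevant candidates are filtered (majority stop words / punctuation /
numbers, or a stop word / preposition at either boundary).  Survivors are
ranked by frequency within each N stratum; a candidate is selected when its
rank lies within the top 70% of its stratum or its absolute frequency
reaches the frequency cut.  Final interface terms additionally require an
expert "accepted" review decision, which is read back from a review sheet —
the pipeline never auto-accepts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from ._text import is_punct_char, join_surfaces
from .tokenize import DocumentTokens, Token

FILTER_REASONS = (
    "stopword_fraction",
    "boundary_stopword",
    "boundary_preposition",
    "punctuation_numbers",
)

#: Default English stop words / prepositions.  These are deliberately small
#: shipped defaults for Latin text and the synthetic language; real-language
#: resources are user-supplied.
DEFAULT_STOPWORDS = frozenset(
    "a an and are as at be but by for if in is it no not of on or so the then "
    "to was were with".split()
)
DEFAULT_PREPOSITIONS = frozenset(
    "at by for from in into of off on onto over to under with".split()
)


class HarvestError(ValueError):
    pass


@dataclass
class CandidateTerm:
    token_surfaces: Tuple[str, ...]
    frequency: int
    rank_within_n: Optional[int] = None
    percentile_within_n: Optional[float] = None
    filtered_reason: Optional[str] = None
    selected: bool = False
    review_status: str = "pending"

    def __post_init__(self) -> None:
        if not 1 <= self.n <= 5:
            raise HarvestError(f"gram length {self.n} outside 1..5")
        if self.frequency < 1:
            raise HarvestError("candidate frequency must be >= 1")

    @property
    def n(self) -> int:
        return len(self.token_surfaces)

    @property
    def surface(self) -> str:
        return join_surfaces(self.token_surfaces)


@dataclass(frozen=True)
class SelectionConfig:
    n_max: int = 5
    stopword_fraction_max: float = 0.5
    percentile_cut: float = 70.0
    frequency_cut: int = 300
    stopwords: FrozenSet[str] = DEFAULT_STOPWORDS
    prepositions: FrozenSet[str] = DEFAULT_PREPOSITIONS
    #: "rank_share": percentile is 100*rank/stratum-size and the cut keeps the
    #: first percentile_cut% of the ranked list (the default reading);
    #: "frequency_percentile" instead keeps candidates whose frequency exceeds
    #: the (100 - percentile_cut)th frequency percentile of the stratum.
    percentile_rule: str = "rank_share"


TokenSequences = Sequence[Sequence[Union[Token, str]]]


def _surfaces(seq: Sequence[Union[Token, str]]) -> List[str]:
    return [t.surface if isinstance(t, Token) else t for t in seq]


def generate_ngrams(
    tokens_per_doc: Union[Sequence[DocumentTokens], TokenSequences],
    n_max: int = 5,
) -> List[CandidateTerm]:
    """Count all overlapping N-gram windows (N = 1..n_max) per sequence.

    Accepts the output of :func:`~uit.tokenize.tokenize_corpus` or plain
    per-document token/surface lists.  Windows never cross sequence
    boundaries (documents, or sections within a document).
    """
    if n_max < 1:
        raise HarvestError("n_max must be >= 1")
    sequences: List[List[str]] = []
    for item in tokens_per_doc:
        if isinstance(item, DocumentTokens):
            sequences.extend(item.section_surfaces())
        else:
            sequences.append(_surfaces(item))
    counts: Counter = Counter()
    for seq in sequences:
        for n in range(1, min(n_max, 5) + 1):
            for i in range(len(seq) - n + 1):
                counts[tuple(seq[i : i + n])] += 1
    return [
        CandidateTerm(gram, freq)
        for gram, freq in sorted(counts.items(), key=lambda kv: (len(kv[0]), kv[0]))
    ]


def _is_number(tok: str) -> bool:
    return bool(tok) and all(c.isdigit() for c in tok)


def _is_punct(tok: str) -> bool:
    return bool(tok) and all(is_punct_char(c) for c in tok)


def filter_candidates(
    candidates: Sequence[CandidateTerm], config: SelectionConfig
) -> List[CandidateTerm]:
    """Set ``filtered_reason`` on syntactically irrelevant candidates.

    A candidate is filtered when the fraction of its tokens that are stop
    words, pure punctuation, or pure numbers exceeds
    ``stopword_fraction_max``, or when its first or last token is a stop word
    or preposition.  Surviving candidates keep ``filtered_reason`` unset.
    """
    stop = {s.casefold() for s in config.stopwords}
    prep = {s.casefold() for s in config.prepositions}
    out = []
    for cand in candidates:
        toks = [t.casefold() for t in cand.token_surfaces]
        reason = None
        n_stop = sum(1 for t in toks if t in stop)
        n_junk = sum(1 for t in toks if t not in stop and (_is_number(t) or _is_punct(t)))
        if (n_stop + n_junk) / cand.n > config.stopword_fraction_max:
            reason = "stopword_fraction" if n_stop else "punctuation_numbers"
        elif toks[0] in stop or toks[-1] in stop:
            reason = "boundary_stopword"
        elif toks[0] in prep or toks[-1] in prep:
            reason = "boundary_preposition"
        out.append(replace(cand, filtered_reason=reason, selected=False))
    return out


def rank_candidates(candidates: Sequence[CandidateTerm]) -> List[CandidateTerm]:
    """Rank surviving candidates within each N stratum.

    Rank 1 is the most frequent; ties break lexicographically on the display
    surface for determinism.  ``percentile_within_n`` is 100*rank/stratum
    size.  Filtered candidates keep rank/percentile unset.
    """
    by_n: Dict[int, List[CandidateTerm]] = {}
    for cand in candidates:
        if cand.filtered_reason is None:
            by_n.setdefault(cand.n, []).append(cand)
    ranked: Dict[Tuple[str, ...], Tuple[int, float]] = {}
    for n, stratum in by_n.items():
        stratum.sort(key=lambda c: (-c.frequency, c.surface))
        size = len(stratum)
        for rank, cand in enumerate(stratum, start=1):
            ranked[cand.token_surfaces] = (rank, 100.0 * rank / size)
    out = []
    for cand in candidates:
        if cand.token_surfaces in ranked:
            rank, pctile = ranked[cand.token_surfaces]
            out.append(replace(cand, rank_within_n=rank, percentile_within_n=pctile))
        else:
            out.append(replace(cand, rank_within_n=None, percentile_within_n=None))
    return out


def _stratum_frequency_cut(
    candidates: Sequence[CandidateTerm], n: int, config: SelectionConfig
) -> float:
    import numpy as np

    freqs = [c.frequency for c in candidates if c.filtered_reason is None and c.n == n]
    if not freqs:
        return float("inf")
    return float(np.percentile(freqs, 100.0 - config.percentile_cut))


def select_terms(
    candidates: Sequence[CandidateTerm], config: SelectionConfig
) -> List[CandidateTerm]:
    """Apply the inclusion criteria.

    selected <=> not filtered AND (within the top percentile cut of the
    stratum OR absolute frequency >= frequency_cut).
    """
    if config.percentile_rule not in ("rank_share", "frequency_percentile"):
        raise HarvestError(f"unknown percentile rule {config.percentile_rule!r}")
    cuts = {}
    if config.percentile_rule == "frequency_percentile":
        cuts = {
            n: _stratum_frequency_cut(candidates, n, config)
            for n in {c.n for c in candidates}
        }
    out = []
    for cand in candidates:
        if cand.filtered_reason is not None:
            out.append(replace(cand, selected=False))
            continue
        if cand.rank_within_n is None:
            raise HarvestError("select_terms requires ranked candidates")
        if config.percentile_rule == "rank_share":
            in_percentile = cand.percentile_within_n <= config.percentile_cut
        else:
            in_percentile = cand.frequency > cuts[cand.n]
        out.append(
            replace(cand, selected=in_percentile or cand.frequency >= config.frequency_cut)
        )
    return out


def harvest_and_select(
    tokens_per_doc, config: SelectionConfig
) -> List[CandidateTerm]:
    """generate -> filter -> rank -> select in the fixed order."""
    cands = generate_ngrams(tokens_per_doc, config.n_max)
    cands = filter_candidates(cands, config)
    cands = rank_candidates(cands)
    return select_terms(cands, config)


# ---------------------------------------------------------------------------
# review sheet round trip
# ---------------------------------------------------------------------------

_SEP = "␟"  # symbol-for-unit-separator: joins token surfaces in sheets


def export_review_sheet(candidates: Sequence[CandidateTerm], path) -> None:
    pd.DataFrame(
        {
            "surface": [c.surface for c in candidates],
            "tokens": [_SEP.join(c.token_surfaces) for c in candidates],
            "n": [c.n for c in candidates],
            "frequency": [c.frequency for c in candidates],
            "rank_within_n": [c.rank_within_n for c in candidates],
            "percentile_within_n": [c.percentile_within_n for c in candidates],
            "filtered_reason": [c.filtered_reason or "" for c in candidates],
            "selected": [c.selected for c in candidates],
            "review_status": [c.review_status for c in candidates],
        }
    ).to_csv(path, index=False)


def import_review_decisions(
    candidates: Sequence[CandidateTerm], path
) -> List[CandidateTerm]:
    """Apply reviewed accept/reject decisions; unknown candidates are errors."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    known = {c.token_surfaces for c in candidates}
    decisions: Dict[Tuple[str, ...], str] = {}
    for _, row in df.iterrows():
        key = tuple(row["tokens"].split(_SEP))
        if key not in known:
            raise HarvestError(f"review decision for unknown candidate {row['surface']!r}")
        status = row["review_status"].strip().lower()
        if status not in ("pending", "accepted", "rejected"):
            raise HarvestError(f"unknown review status {row['review_status']!r}")
        decisions[key] = status
    return [
        replace(c, review_status=decisions.get(c.token_surfaces, c.review_status))
        for c in candidates
    ]


def interface_terms(candidates: Sequence[CandidateTerm]) -> List[CandidateTerm]:
    """Final interface terms: selected by the criteria AND expert-accepted."""
    return [c for c in candidates if c.selected and c.review_status == "accepted"]
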