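"""End-to-end driver: raw corpus -> cleaned corpus -> tokens -> selected terms.

Order is fixed (and the reason is mechanical): abbreviation harvesting needs
capital letters, so it precedes case normalization; spelling must be fixed
before dictionary segmentation; duplicate visits are removed before anything
is counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set, Tuple

from .corpus import Corpus
from .harvest import CandidateTerm, SelectionConfig, harvest_and_select
from .lexicon import AbbreviationCandidate, Lexicon, harvest_abbreviations
from .preprocess import NormalizationRule, PreprocessReport, run_preprocess
from .tokenize import DocumentTokens, TokenizerConfig, DEFAULT_CONFIG, tokenize_corpus


@dataclass
class PipelineResult:
    corpus: Corpus  # cleaned
    report: PreprocessReport
    abbreviation_candidates: List[AbbreviationCandidate]
    doc_tokens: List[DocumentTokens]
    candidates: List[CandidateTerm]

    @property
    def selected(self) -> Set[Tuple[str, ...]]:
        return {c.token_surfaces for c in self.candidates if c.selected}


def run_pipeline(
    corpus: Corpus,
    lexicon: Lexicon,
    selection_config: Optional[SelectionConfig] = None,
    tokenizer_config: TokenizerConfig = DEFAULT_CONFIG,
    rules: Sequence[NormalizationRule] = (),
) -> PipelineResult:
    selection_config = selection_config or SelectionConfig()
    abbrevs = harvest_abbreviations(corpus)
    cleaned, report = run_preprocess(corpus, lexicon, rules)
    doc_tokens = tokenize_corpus(cleaned, lexicon, tokenizer_config)
    candidates = harvest_and_select(doc_tokens, selection_config)
    return PipelineResult(cleaned, report, abbrevs, doc_tokens, candidates)
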