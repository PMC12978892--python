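"""Seeded generator of a complete synthetic terminology study.

The generator emulates the statistical structure of a mixed-script
outpatient corpus — a continuous script without word boundaries, Latin
medical jargon, department-dependent script mix, Zipfian term frequencies,
repeated sentences across a patient's visits, misspellings, stop-word
filler — together with the resources the pipeline consumes: the five
lexicon sources, an RF2-style concept catalog, and a gold map table with
designed equivalence proportions.  Everything is deterministic given the
design's seed, and the bookkeeping is sufficient to predict every pipeline
output.

The synthetic continuous script lives in the private-use code-point area, so
tests need no real-language resources.  Exact tokenizer recovery is
guaranteed by construction: every continuous-script word begins with a
2-glyph *initial unit* unique to that word, initial / interior / salt glyph
alphabets are disjoint, and all units are 2 glyphs wide — so the greedy
longest match at any word boundary can only be the word itself.  Each base
sentence ends in a unique throwaway "salt" word, which makes sentences
distinct (only deliberately injected duplicates repeat) and reproduces the
long Zipf tail of once-seen words.
"""

from __future__ import annotations

import itertools
import json
import os
import random
import string
from collections import Counter
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Set, Tuple

from ._text import char_class, join_surfaces
from .corpus import Corpus, Document, write_corpus
from .harvest import DEFAULT_PREPOSITIONS, DEFAULT_STOPWORDS, SelectionConfig
from .lexicon import Lexicon, LexiconEntry, levenshtein_leq, write_word_list
from .mapping import (
    ConceptCatalog,
    Description,
    FSN_TYPE_ID,
    MapEntry,
    MapTable,
    write_concept_catalog,
    write_map_table,
)


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticLanguageSpec:
    #: number of 2-glyph continuous-script units available for word building
    continuous_unit_inventory_size: int = 512
    #: probability of a continuous word being 1..4 units long
    compound_length_distribution: Tuple[float, ...] = (0.45, 0.35, 0.15, 0.05)
    #: inclusive code-point range of the synthetic continuous script (PUA)
    continuous_glyph_range: Tuple[int, int] = (0xE000, 0xE17F)
    latin_jargon_pool_size: int = 220
    stopword_pool: Tuple[str, ...] = tuple(sorted(DEFAULT_STOPWORDS))
    preposition_pool: Tuple[str, ...] = tuple(sorted(DEFAULT_PREPOSITIONS))

    def __post_init__(self) -> None:
        lo, hi = self.continuous_glyph_range
        if hi - lo + 1 < 96:
            raise DesignError("continuous glyph range too small for three alphabets")


@dataclass(frozen=True)
class PlantedTerm:
    tokens: Tuple[str, ...]
    language: str  # "thai" | "english"
    designed_frequency: int
    concept_id: Optional[str]
    equivalence: str
    direct_lexical: bool
    unmapped_category: Optional[str] = None

    @property
    def n(self) -> int:
        return len(self.tokens)

    @property
    def surface(self) -> str:
        return join_surfaces(self.tokens)


def _default_depts_patients() -> Dict[str, int]:
    return {"FM": 12, "ER": 23, "IM": 30}


def _default_depts_docs() -> Dict[str, int]:
    return {"FM": 30, "ER": 35, "IM": 118}


def _default_script_mix() -> Dict[str, float]:
    return {"FM": 0.59, "ER": 0.64, "IM": 0.40}


def _default_equivalence_fractions() -> Dict[str, float]:
    return {
        "full": 0.855,
        "broader": 0.059,
        "narrower": 0.027,
        "inexact": 0.039,
        "unmapped": 0.020,
    }


def _default_unmapped_fractions() -> Dict[str, float]:
    return {"ambiguous": 0.548, "multiconcept": 0.238, "no_concept": 0.214}


@dataclass(frozen=True)
class StudyDesign:
    """Design of one synthetic study; all randomness flows from ``seed``.

    Default sizes are a desk-scale rendition of the source setting: three
    departments with patient/document counts in the proportions of the real
    corpus (roughly 1/1000 of it), department continuous-script word shares
    of 0.59/0.64/0.40, equivalence fractions 0.855/0.059/0.027/0.039/0.020,
    and an N-gram length mix dominated by unigrams and bigrams.
    """

    seed: int = 0
    n_patients: Dict[str, int] = field(default_factory=_default_depts_patients)
    n_documents: Dict[str, int] = field(default_factory=_default_depts_docs)
    n_terms: int = 240
    zipf_exponent: float = 1.1
    max_term_frequency: int = 600
    thai_term_fraction: float = 0.4527
    ngram_length_distribution: Tuple[float, ...] = (0.527, 0.356, 0.091, 0.022, 0.005)
    duplicate_sentence_rate: float = 0.15
    misspelling_rate: float = 0.02
    stopword_filler_rate: float = 0.2
    dept_script_mix: Dict[str, float] = field(default_factory=_default_script_mix)
    equivalence_fractions: Dict[str, float] = field(
        default_factory=_default_equivalence_fractions
    )
    one_to_many_term_fraction: float = 0.014
    #: target share of *entries* that are direct lexical matches, among
    #: English mapped entries
    direct_lexical_fraction: float = 0.575
    unmapped_category_fractions: Dict[str, float] = field(
        default_factory=_default_unmapped_fractions
    )
    concept_reuse_rate: float = 0.27
    planted_abbreviations: Tuple[Tuple[str, int], ...] = (
        ("DOI", 150),
        ("CXR", 120),
        ("BP", 80),  # deliberately below the >100 frequency cut
    )
    language: SyntheticLanguageSpec = field(default_factory=SyntheticLanguageSpec)
    #: selection thresholds the study is designed against (desk-scale cut)
    selection_config: SelectionConfig = field(
        default_factory=lambda: SelectionConfig(frequency_cut=30)
    )

    def __post_init__(self) -> None:
        if abs(sum(self.equivalence_fractions.values()) - 1.0) > 1e-9:
            raise DesignError("equivalence fractions must sum to 1")
        if set(self.n_patients) != set(self.n_documents) or set(
            self.n_documents
        ) != set(self.dept_script_mix):
            raise DesignError("department keys must agree across design fields")
        if self.n_terms < 1:
            raise DesignError("need at least one planted term")


@dataclass
class SyntheticStudy:
    corpus: Corpus  # with injected noise (raw, pre-normalization)
    base_corpus: Corpus  # noise-free twin: no duplicates, no misspellings
    lexicon_sources: Dict[str, List[str]]  # source tag -> word list
    catalog: ConceptCatalog
    gold_map: MapTable
    planted_terms: List[PlantedTerm]
    gold_selected: Set[Tuple[str, ...]]
    bookkeeping: Dict[str, object]
    design: StudyDesign

    def build_lexicon(self) -> Lexicon:
        lex = Lexicon()
        for tag, words in self.lexicon_sources.items():
            for w in words:
                lex.add(LexiconEntry(w, source=tag, is_abbreviation=tag == "abbreviations"))
        return lex


# ---------------------------------------------------------------------------
# language materialization
# ---------------------------------------------------------------------------


class _Language:
    """Deterministic word factories for one study."""

    def __init__(self, spec: SyntheticLanguageSpec, rng: random.Random) -> None:
        lo, hi = spec.continuous_glyph_range
        span = hi - lo + 1
        third = span // 3
        self.initial_glyphs = [chr(lo + i) for i in range(third)]
        self.interior_glyphs = [chr(lo + third + i) for i in range(third)]
        self.salt_glyphs = [chr(lo + 2 * third + i) for i in range(span - 2 * third)]
        n_units = spec.continuous_unit_inventory_size
        pairs = [a + b for a, b in itertools.product(self.initial_glyphs, repeat=2)]
        rng.shuffle(pairs)
        # consumed one per word: the word-unique initial unit guarantees
        # unambiguous greedy segmentation of any word concatenation
        self._initial_units = pairs[: max(n_units // 2, 64)]
        interior = [a + b for a, b in itertools.product(self.interior_glyphs, repeat=2)]
        rng.shuffle(interior)
        self.interior_units = interior[: max(n_units - len(self._initial_units), 8)]
        self.spec = spec
        self.rng = rng
        self._stopish = sorted(set(spec.stopword_pool) | set(spec.preposition_pool))
        self._used_latin: Set[str] = set(self._stopish)
        self._jargon: List[str] = []
        self._salts_used: Set[str] = set()

    def new_continuous_word(self) -> str:
        if not self._initial_units:
            raise DesignError("continuous-script unit inventory exhausted")
        n_units = self.rng.choices(
            range(1, len(self.spec.compound_length_distribution) + 1),
            weights=self.spec.compound_length_distribution,
        )[0]
        word = self._initial_units.pop()
        for _ in range(n_units - 1):
            word += self.rng.choice(self.interior_units)
        return word

    def new_latin_word(
        self, length_range: Tuple[int, int] = (5, 8), jargon: bool = True
    ) -> str:
        """A fresh lowercase Latin word.

        Jargon words (dictionary entries that may be misspelled in the
        corpus) keep pairwise edit distance >=3 from each other and >=2 from
        every stop word, so a single-edit misspelling has exactly one
        dictionary neighbor and spell correction is never ambiguous.
        Catalog-only words (FSNs, non-matching descriptions) never enter the
        dictionary as single words, so they only need to be fresh.
        """
        for _ in range(10_000):
            length = self.rng.randint(*length_range)
            word = "".join(self.rng.choice(string.ascii_lowercase) for _ in range(length))
            if word in self._used_latin:
                continue
            if jargon:
                if any(levenshtein_leq(word, s, 1) for s in self._stopish):
                    continue
                if any(
                    levenshtein_leq(word, other, 2)
                    for other in self._jargon
                    if abs(len(other) - length) <= 2
                ):
                    continue
                self._jargon.append(word)
            self._used_latin.add(word)
            return word
        raise DesignError("latin jargon pool exhausted")

    def new_salt(self, continuous: bool) -> str:
        for _ in range(10_000):
            if continuous:
                word = "".join(self.rng.choice(self.salt_glyphs) for _ in range(3))
            else:
                word = "".join(self.rng.choice(string.ascii_lowercase) for _ in range(3))
                if word in self._used_latin:
                    continue
            if word not in self._salts_used:
                self._salts_used.add(word)
                return word
        raise DesignError("salt vocabulary exhausted")


def _largest_remainder(fractions: Dict[str, float], total: int) -> Dict[str, int]:
    """Integer counts matching ``fractions`` of ``total`` exactly."""
    raw = {k: v * total for k, v in fractions.items()}
    counts = {k: int(v) for k, v in raw.items()}
    short = total - sum(counts.values())
    order = sorted(raw, key=lambda k: (raw[k] - counts[k], k), reverse=True)
    for k in order[:short]:
        counts[k] += 1
    return counts


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------


def make_study(design: StudyDesign) -> SyntheticStudy:
    rng = random.Random(design.seed)
    lang = _Language(design.language, rng)

    # --- planted terms -----------------------------------------------------
    n_thai = round(design.n_terms * design.thai_term_fraction)
    languages = ["thai"] * n_thai + ["english"] * (design.n_terms - n_thai)
    rng.shuffle(languages)
    ranks = list(range(1, design.n_terms + 1))
    rng.shuffle(ranks)
    term_specs = []
    for language, rank in zip(languages, ranks):
        n = rng.choices(
            range(1, len(design.ngram_length_distribution) + 1),
            weights=design.ngram_length_distribution,
        )[0]
        if language == "thai":
            tokens = tuple(lang.new_continuous_word() for _ in range(n))
        else:
            tokens = tuple(lang.new_latin_word() for _ in range(n))
        freq = max(1, round(design.max_term_frequency * rank ** -design.zipf_exponent))
        term_specs.append((tokens, language, freq))

    total_docs = sum(design.n_documents.values())
    total_occurrence_tokens = sum(len(t) * f for t, _, f in term_specs)
    if total_docs == 0 or total_occurrence_tokens / total_docs > 400:
        raise DesignError(
            "designed term frequencies exceed corpus capacity "
            f"({total_occurrence_tokens} planted tokens over {total_docs} documents)"
        )

    # --- gold map and concept catalog -------------------------------------
    n_one_to_many = round(design.n_terms * design.one_to_many_term_fraction)
    n_entries = design.n_terms + n_one_to_many
    cat_counts = _largest_remainder(design.equivalence_fractions, n_entries)
    n_unmapped = cat_counts["unmapped"]

    idx = list(range(design.n_terms))
    rng.shuffle(idx)
    unmapped_idx = set(idx[:n_unmapped])
    one_to_many_idx = set(idx[n_unmapped : n_unmapped + n_one_to_many])
    unmapped_cats = _largest_remainder(design.unmapped_category_fractions, n_unmapped)
    unmapped_cat_list = [c for c, k in sorted(unmapped_cats.items()) for _ in range(k)]
    rng.shuffle(unmapped_cat_list)
    mapped_cat_list = [
        c
        for c in ("full", "broader", "narrower", "inexact")
        for _ in range(cat_counts[c])
    ]
    rng.shuffle(mapped_cat_list)

    english_mapped_entries = sum(
        (2 if i in one_to_many_idx else 1)
        for i, (_, language, _) in enumerate(term_specs)
        if language == "english" and i not in unmapped_idx
    )
    direct_target = round(design.direct_lexical_fraction * english_mapped_entries)
    english_mapped_terms = [
        i
        for i, (_, language, _) in enumerate(term_specs)
        if language == "english" and i not in unmapped_idx
    ]
    rng.shuffle(english_mapped_terms)
    direct_terms: Set[int] = set()
    acc = 0
    for i in english_mapped_terms:
        if acc >= direct_target:
            break
        direct_terms.add(i)
        acc += 2 if i in one_to_many_idx else 1

    catalog = ConceptCatalog()
    concept_ids: List[str] = []
    next_concept = itertools.count(100001)
    next_desc = itertools.count(500001)
    entries: List[MapEntry] = []
    planted: List[PlantedTerm] = []
    mapped_cats = iter(mapped_cat_list)
    unmapped_cats_iter = iter(unmapped_cat_list)

    def fresh_concept() -> str:
        cid = str(next(next_concept))
        fsn = (
            f"{lang.new_latin_word((6, 9), jargon=False)} "
            f"{lang.new_latin_word((6, 9), jargon=False)} (finding)"
        )
        catalog.add(
            Description(str(next(next_desc)), cid, fsn, type_id=FSN_TYPE_ID)
        )
        concept_ids.append(cid)
        return cid

    for i, (tokens, language, freq) in enumerate(term_specs):
        surface = join_surfaces(tokens)
        if i in unmapped_idx:
            category = next(unmapped_cats_iter)
            entries.append(
                MapEntry(surface, language, len(tokens), None, "unmapped", "none", category)
            )
            planted.append(
                PlantedTerm(tokens, language, freq, None, "unmapped", False, category)
            )
            continue
        k_targets = 2 if i in one_to_many_idx else 1
        term_cids = []
        for _ in range(k_targets):
            reuse = (
                concept_ids
                and rng.random() < design.concept_reuse_rate
                and any(c not in term_cids for c in concept_ids)
            )
            if reuse:
                cid = rng.choice([c for c in concept_ids if c not in term_cids])
            else:
                cid = fresh_concept()
            term_cids.append(cid)
            equivalence = next(mapped_cats)
            match_type = "direct_lexical" if i in direct_terms else "contextual"
            entries.append(
                MapEntry(surface, language, len(tokens), cid, equivalence, match_type)
            )
        # one description for the first target concept: a writing variation
        # of the term for direct matches, unrelated words otherwise
        if i in direct_terms:
            words = list(tokens)
            rng.shuffle(words)
            words[0] = words[0].capitalize()
            desc_term = " ".join(words)
        else:
            desc_term = (
                f"{lang.new_latin_word((6, 9), jargon=False)} "
                f"{lang.new_latin_word((6, 9), jargon=False)}"
            )
        catalog.add(Description(str(next(next_desc)), term_cids[0], desc_term))
        planted.append(
            PlantedTerm(
                tokens,
                language,
                freq,
                term_cids[0],
                entries[-k_targets].equivalence,
                i in direct_terms,
            )
        )
    gold_map = MapTable(entries)

    # --- lexicon sources ---------------------------------------------------
    thai_words = sorted({t for p in planted if p.language == "thai" for t in p.tokens})
    latin_words = sorted({t for p in planted if p.language == "english" for t in p.tokens})
    n_drug = max(1, len(latin_words) // 4)
    lexicon_sources = {
        "wordnet_en": latin_words[n_drug:],
        "wordnet_local": thai_words,
        "concept_descriptions": sorted({d.term for d in catalog.descriptions}),
        "drug_db": latin_words[:n_drug],
        "abbreviations": sorted({a for a, _ in design.planted_abbreviations}),
    }

    # --- occurrence layout -------------------------------------------------
    depts = sorted(design.n_documents)
    patients = {
        d: [f"P{d}{i:04d}" for i in range(design.n_patients.get(d, 1))] for d in depts
    }
    doc_ids = {d: [f"D{d}{i:05d}" for i in range(design.n_documents[d])] for d in depts}

    occurrences: Dict[str, List[object]] = {d: [] for d in depts}
    for p in planted:
        for _ in range(p.designed_frequency):
            weights = [
                design.n_documents[d]
                * (
                    design.dept_script_mix[d]
                    if p.language == "thai"
                    else 1 - design.dept_script_mix[d]
                )
                for d in depts
            ]
            dept = rng.choices(depts, weights=weights)[0]
            occurrences[dept].append(p)
    for surface, count in design.planted_abbreviations:
        for _ in range(count):
            dept = rng.choices(depts, weights=[design.n_documents[d] for d in depts])[0]
            occurrences[dept].append(surface)  # plain string marks an abbreviation

    # --- sentence / document assembly --------------------------------------
    corrections_expected = 0
    misspelled_occurrences = 0

    def render(tokens: Sequence[str]) -> str:
        return join_surfaces(tokens)

    def corrupt(word: str) -> str:
        pos = rng.randint(1, len(word) - 2)
        repl = rng.choice([c for c in string.ascii_lowercase if c != word[pos]])
        return word[:pos] + repl + word[pos + 1 :]

    base_docs: List[Document] = []
    noisy_docs: List[Document] = []
    dup_inserted = 0
    dup_chars = 0

    for dept in depts:
        items = occurrences[dept]
        rng.shuffle(items)
        docs = doc_ids[dept]
        per_doc: List[List[object]] = [[] for _ in docs]
        for i, item in enumerate(items):
            per_doc[i % len(docs)].append(item)
        doc_patient = [rng.choice(patients[dept]) for _ in docs]
        # per-patient visit history of non-abbreviation base sentences
        history: Dict[str, List[str]] = {p: [] for p in patients[dept]}

        for doc_id, patient, doc_items in zip(docs, doc_patient, per_doc):
            base_sentences: List[str] = []
            sentences: List[str] = []
            dup_eligible: List[str] = []
            chunk: List[object] = []
            chunks: List[List[object]] = []
            for item in doc_items:
                chunk.append(item)
                if len(chunk) >= rng.randint(1, 3):
                    chunks.append(chunk)
                    chunk = []
            if chunk:
                chunks.append(chunk)
            if not chunks:
                chunks = [[]]
            for chunk in chunks:
                tokens: List[str] = []
                has_abbrev = False
                misspell_flags: List[int] = []
                for item in chunk:
                    if isinstance(item, str):
                        tokens.append(item)
                        has_abbrev = True
                        continue
                    for tok in item.tokens:
                        if (
                            item.language == "english"
                            and rng.random() < design.misspelling_rate
                        ):
                            misspell_flags.append(len(tokens))
                        tokens.append(tok)
                    if rng.random() < design.stopword_filler_rate:
                        tokens.append(rng.choice(design.language.stopword_pool))
                continuous_salt = rng.random() < design.dept_script_mix[dept]
                tokens.append(lang.new_salt(continuous_salt))
                base_sentence = render(tokens)
                if misspell_flags:
                    noisy_tokens = list(tokens)
                    for pos in misspell_flags:
                        noisy_tokens[pos] = corrupt(noisy_tokens[pos])
                        corrections_expected += 1
                        misspelled_occurrences += 1
                    noisy_sentence = render(noisy_tokens)
                else:
                    noisy_sentence = base_sentence
                sentences.append(noisy_sentence)
                # only clean sentences may be re-quoted in later visits:
                # duplicate elimination runs before spell correction, so a
                # copy must equal its earlier occurrence verbatim
                if not has_abbrev and not misspell_flags:
                    dup_eligible.append(base_sentence)
                base_sentences.append(base_sentence)

            noisy_sentences = list(sentences)
            # duplicate injection: copies of sentences from earlier visits
            earlier = history[patient]
            if earlier:
                for _ in range(len(noisy_sentences)):
                    if rng.random() < design.duplicate_sentence_rate:
                        copy = rng.choice(earlier)
                        pos = rng.randint(1, len(noisy_sentences))
                        noisy_sentences.insert(pos, copy)
                        dup_inserted += 1
                        dup_chars += len(copy) + 1
            history[patient].extend(dup_eligible)

            def to_doc(sent_list: List[str]) -> Document:
                cc = sent_list[0] if sent_list else ""
                pi = "\n".join(sent_list[1:])
                return Document(doc_id, patient, dept, cc, pi)

            base_docs.append(to_doc(base_sentences))
            noisy_docs.append(to_doc(noisy_sentences))

    base_corpus = Corpus(base_docs)
    noisy_corpus = Corpus(noisy_docs)

    bookkeeping: Dict[str, object] = {
        "designed_frequencies": {p.surface: p.designed_frequency for p in planted},
        "duplicates_inserted": dup_inserted,
        "duplicate_chars": dup_chars,
        "corrections_expected": corrections_expected,
        "misspelled_occurrences": misspelled_occurrences,
        "abbreviation_counts": {a: c for a, c in design.planted_abbreviations},
        "equivalence_counts": cat_counts,
        "n_entries": n_entries,
        "n_one_to_many_terms": n_one_to_many,
        "direct_entry_target": direct_target,
    }

    study = SyntheticStudy(
        corpus=noisy_corpus,
        base_corpus=base_corpus,
        lexicon_sources=lexicon_sources,
        catalog=catalog,
        gold_map=gold_map,
        planted_terms=planted,
        gold_selected=set(),
        bookkeeping=bookkeeping,
        design=design,
    )
    study.gold_selected = predict_pipeline_outputs(study, design.selection_config).selected
    return study


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write corpus, word lists, RF2-style catalog, gold map, bookkeeping."""
    os.makedirs(outdir, exist_ok=True)
    write_corpus(study.corpus, os.path.join(outdir, "corpus.jsonl"))
    write_corpus(study.base_corpus, os.path.join(outdir, "base_corpus.jsonl"))
    lexdir = os.path.join(outdir, "lexicon")
    os.makedirs(lexdir, exist_ok=True)
    for tag, words in study.lexicon_sources.items():
        write_word_list(words, os.path.join(lexdir, f"{tag}.txt"))
    write_concept_catalog(study.catalog, os.path.join(outdir, "descriptions.tsv"))
    write_map_table(study.gold_map, os.path.join(outdir, "gold_map.csv"))
    with open(os.path.join(outdir, "bookkeeping.json"), "w", encoding="utf-8") as fh:
        json.dump(study.bookkeeping, fh, ensure_ascii=False, sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# prediction oracle
# ---------------------------------------------------------------------------


def reference_segment(text: str, entries: Set[str], max_len: int) -> List[str]:
    """Independent greedy longest-match segmenter used as a test oracle.

    Splits on whitespace and script-class changes first, then segments each
    run recursively; unmatched stretches merge until a dictionary match
    begins.  Deliberately structured differently from the production
    tokenizer.
    """

    def seg_run(s: str) -> List[str]:
        out: List[str] = []
        while s:
            match = next(
                (
                    s[:L]
                    for L in range(min(max_len, len(s)), 0, -1)
                    if s[:L] in entries
                ),
                None,
            )
            if match is not None:
                out.append(match)
                s = s[len(match) :]
                continue
            k = 1
            while k < len(s) and not any(
                s[k : k + L] in entries
                for L in range(1, min(max_len, len(s) - k) + 1)
            ):
                k += 1
            out.append(s[:k])
            s = s[k:]
        return out

    tokens: List[str] = []
    for run_class, group in itertools.groupby(text, key=char_class):
        run = "".join(group)
        if run_class == "space":
            continue
        tokens.extend(seg_run(run))
    return tokens


@dataclass
class ExpectedOutputs:
    candidate_freqs: Counter
    selected: Set[Tuple[str, ...]]
    duplicates_removed: int
    corrections_applied: int
    coverage_counts: Dict[str, int]
    coverage_percents: Dict[str, float]


def predict_pipeline_outputs(
    study: SyntheticStudy, config: SelectionConfig
) -> ExpectedOutputs:
    """Brute-force recomputation of the expected pipeline outputs.

    Tokenization goes through :func:`reference_segment` on the noise-free
    base corpus (duplicates are exactly the injected copies and every planted
    misspelling has a unique correction, so the cleaned pipeline corpus
    equals the base corpus); counting and the selection predicate are applied
    directly.
    """
    entries = {
        w.casefold()
        for words in study.lexicon_sources.values()
        for w in words
        if " " not in w
    }
    max_len = max(len(w) for w in entries)

    counts: Counter = Counter()
    for doc in study.base_corpus:
        for section in doc.sections:
            tokens: List[str] = []
            for line in section.lower().split("\n"):
                tokens.extend(reference_segment(line, entries, max_len))
            for n in range(1, config.n_max + 1):
                for i in range(len(tokens) - n + 1):
                    counts[tuple(tokens[i : i + n])] += 1

    stop = {s.casefold() for s in config.stopwords}
    prep = {s.casefold() for s in config.prepositions}

    def survives(gram: Tuple[str, ...]) -> bool:
        junk = sum(
            1 for t in gram if t in stop or t.isdigit()
        )
        if junk / len(gram) > config.stopword_fraction_max:
            return False
        return not (
            gram[0] in stop or gram[-1] in stop or gram[0] in prep or gram[-1] in prep
        )

    selected: Set[Tuple[str, ...]] = set()
    for n in {len(g) for g in counts}:
        stratum = sorted(
            (g for g in counts if len(g) == n and survives(g)),
            key=lambda g: (-counts[g], join_surfaces(g)),
        )
        size = len(stratum)
        for rank, gram in enumerate(stratum, start=1):
            if (
                100.0 * rank / size <= config.percentile_cut
                or counts[gram] >= config.frequency_cut
            ):
                selected.add(gram)

    cov_counts = Counter(e.equivalence for e in study.gold_map)
    n = len(study.gold_map)
    q = Decimal("0.01")
    cov_pct = {
        c: float((Decimal(k) * 100 / Decimal(n)).quantize(q, rounding=ROUND_HALF_UP))
        for c, k in cov_counts.items()
    }
    return ExpectedOutputs(
        candidate_freqs=counts,
        selected=selected,
        duplicates_removed=int(study.bookkeeping["duplicates_inserted"]),
        corrections_applied=int(study.bookkeeping["corrections_expected"]),
        coverage_counts=dict(cov_counts),
        coverage_percents=cov_pct,
    )


def planted_recall(
    study: SyntheticStudy,
    selected: Set[Tuple[str, ...]],
    config: Optional[SelectionConfig] = None,
) -> float:
    """Recall of planted terms whose designed frequency reaches the
    absolute-frequency cut (those must be selected regardless of rank)."""
    config = config or study.design.selection_config
    high = [
        p for p in study.planted_terms if p.designed_frequency >= config.frequency_cut
    ]
    if not high:
        return 1.0
    return sum(1 for p in high if p.tokens in selected) / len(high)
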