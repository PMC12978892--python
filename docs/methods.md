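# Methods

## The pipeline and its assumptions

The package models terminology harvesting as a deterministic function of a
document corpus and a dictionary. A corpus is an ordered list of outpatient
notes, each with a department code (FM family medicine, ER emergency, IM
internal medicine), a patient id, and two free-text sections (chief
complaint, present illness). Patient ids repeat across documents; documents
with both sections empty are excluded at load time.

**Dictionary.** The custom dictionary D unions five word-list sources
(general-English words, local-language words, reference-terminology
descriptions, drug terminology, reviewed abbreviations). Entries are keyed
case-folded for Latin text and verbatim for continuous script (which has no
case). Duplicate surfaces keep the first source tag, so membership is
independent of source order. Multiword entries (English jargon from concept
descriptions) are stored whole; whether the tokenizer may use them is a
tokenizer flag.

**Cleaning order** is fixed: abbreviation harvest → normalize → visit
dedup → spell-check → tokenize. Abbreviation harvesting (≥2 capital Latin
letters, corpus frequency strictly >100, over whitespace/punctuation
delimited raw tokens) must precede case normalization or the capitals rule
has nothing to match. Spelling must be fixed before segmentation because an
unknown (misspelled) Latin token would otherwise surface as an
out-of-dictionary token and distort N-gram counts.

**Normalization** lowercases Latin letters, maps every Unicode punctuation
character to a space, collapses space runs, and applies an ordered list of
pluggable rewrite rules. The rule list is identity by default; real-language
tone-mark/vowel reordering can be supplied as rules without the core
depending on any language resource. Digits are kept — the candidate filter
needs them. Newlines survive as sentence delimiters.

**Visit dedup** removes, within one patient and in corpus order, any
sentence (newline-delimited) identical to a sentence of an *earlier*
document of the same patient; first occurrences and within-document repeats
are kept. Sentence granularity is the default; whole-entry dedup is
available via a flag. This is deliberately conservative: continuous script
has no sentence punctuation, so only explicit line breaks are trusted as
boundaries.

**Spell correction** applies to space-delimited, purely Latin tokens of
length ≥4 (correcting shorter tokens or abbreviations at edit distance 1 is
unsafe); a token is replaced only when exactly one dictionary entry lies
within edit distance 1 (bounded Levenshtein), otherwise left unchanged and
logged. Corrections are folded to lowercase because they are applied to an
already case-normalized corpus.

**Tokenization** is greedy maximum matching: at each position the longest
dictionary entry matching exactly is emitted; ties are impossible (matching
is exact substring). Whitespace is always a boundary and is consumed, never
emitted. A script change (continuous ↔ Latin ↔ digit) is treated like
whitespace by default, configurable. When nothing matches, the default
fallback merges the maximal unmatched same-script run into one unknown
token (keeping N-grams meaningful); single-character emission is available.
Offsets are 0-based half-open so every tokenization is auditable against
its source: the surfaces plus skipped whitespace reconstruct the input.

**Candidate selection.** N-grams (N = 1–5) are counted over overlapping
windows within each document section, never across documents or across the
chief-complaint/present-illness boundary. A candidate is filtered when more
than half its tokens are stop words, pure punctuation or pure numbers, or
when its first or last token is a stop word or preposition. Filtering comes
before ranking, so percentiles are computed over plausible candidates only.
Within each N stratum survivors are sorted by frequency (ties broken
lexicographically on the display surface, for determinism), and
percentile = 100·rank/stratum size. A candidate is selected iff it survives
filtering and (percentile ≤ 70 **or** frequency ≥ the absolute cut). The
"top 70th percentile" is read as rank position within the first 70% of the
ranked list; the alternative reading (frequency above the stratum's 70th
frequency percentile) is available via `SelectionConfig.percentile_rule`.
Final interface terms require an expert "accepted" decision imported from a
review sheet; the pipeline never accepts automatically.

**Mapping and coverage.** The concept catalog is read from an RF2-style
description snapshot (FSN rows define concepts and their parenthesized
semantic tag; synonym rows add descriptions; inactive rows are dropped and
counted). Map-table rows carry one source-term → concept pair each, with
relationship labels translated bijectively to the five equivalence
categories; a term with k targets contributes k rows, and a term is never
both mapped and unmapped. Source-term language is script-derived: ≥1
continuous-script character ⇒ local language, mixed script included (the
binary split needs a rule for mixed tokens; script presence is the sharpest
one). All coverage percentages use total map entries as denominator — that
is the only denominator under which the published-style percentages are
internally consistent — rounded half-up to two decimals. Term coverage
calls a source term a direct lexical match when its normalized word
multiset (case-folded, punctuation-stripped, order-insensitive) equals that
of any active description; stemming is deliberately excluded to keep the
definition sharp. Because the alternative "share of English entries"
denominator is also of interest, the report carries both.

## The synthetic study

Real clinical records cannot be redistributed, so the generator builds a
study with the statistical structure the analysis assumes; it makes no
attempt to imitate real orthography or real terminology content.

* **Language.** The continuous script lives in the private-use area
  (U+E000…), split into three disjoint glyph alphabets: word-initial units,
  word-interior units, and salt glyphs. Every word is a compound of 1–4
  two-glyph units whose *initial unit is unique to that word*. Any
  concatenation of such words then has a unique greedy segmentation (an
  entry matching at a word boundary must begin with that word's unique
  initial unit, hence is that word), which is what lets tests demand exact
  token recovery. Latin jargon words (5–8 letters) keep pairwise edit
  distance ≥3 and distance ≥2 from every stop word, so any single-edit
  misspelling has exactly one dictionary neighbor and spell correction is
  deterministic.
* **Corpus.** Planted terms (default 240; ~45% local-script) get Zipfian
  designed frequencies (exponent 1.1, reproducing the long-tailed
  rank-frequency shape), are assigned to departments with
  department-specific script mixes (0.59/0.64/0.40 continuous-script
  weight for FM/ER/IM), and are laid out in 1–3-term sentences with
  stop-word filler. Each sentence ends in a unique throwaway salt word:
  sentences are therefore pairwise distinct, the injected visit duplicates
  are exactly the sentences the deduper should remove, and the corpus
  acquires a realistic tail of once-seen unknown tokens. Misspelling noise
  corrupts one interior letter of a Latin token occurrence (default rate
  2%); duplicated sentences are drawn only from clean, abbreviation-free
  sentences of the same patient's earlier documents so that dedup counts
  are exactly predictable. Uppercase abbreviations (DOI ×150, CXR ×120,
  BP ×80 — the last deliberately under the >100 cut) are planted in raw
  text.
* **Gold map.** Entry counts per equivalence category follow the designed
  fractions (default 0.855/0.059/0.027/0.039/0.020) exactly via
  largest-remainder rounding; ~1.4% of terms are one-to-many; ~57% of
  English mapped entries get a description that is a word-order/case
  variation of the term (direct lexical match), the rest get unrelated
  fresh words; concepts are reused across entries at rate 0.27 so unique
  concepts < mapped entries. Local-script terms never match descriptions
  (descriptions are Latin), mirroring an untranslated reference
  terminology.
* **Oracle.** `predict_pipeline_outputs` recomputes every expected output
  independently: an independently written recursive reference segmenter,
  direct Counter-based N-gram counts on the noise-free twin corpus, the
  selection predicate applied literally, and coverage recounts of the gold
  map. Because duplicates and misspellings are constructed to be exactly
  reversible, the cleaned pipeline corpus equals the noise-free twin and
  the pipeline must agree with the oracle *exactly*, noise or no noise;
  the tests assert this across seeds.

What passing these tests shows — and does not. They show the algorithms
are implemented exactly (segmentation ≡ oracle on 1000+ random cases,
selection predicate compliance on every run, exact noise recovery, exact
coverage arithmetic). They do not show that real Thai clinical text
segments well (that depends on real dictionary quality), nor that the
selection thresholds are clinically optimal — those remain properties of
the data and the experts, not of the code.

## Sizes, defaults, numerical choices

* Desk-scale study defaults: 65 patients / 183 documents (FM 12/30,
  ER 23/35, IM 30/118 — the real setting's proportions at 1/1000 scale),
  240 planted terms, top designed frequency 600, ~35 k characters. One
  generation + pipeline run takes ~1.5 s; the whole suite runs in well
  under a minute.
* The absolute frequency cut used with synthetic studies is 30
  (`StudyDesign.selection_config`); the class default of
  `SelectionConfig.frequency_cut` stays at the field-standard 300, which
  only makes sense at full corpus scale.
* Percentages: decimal half-up rounding at 2 decimals (1 decimal where the
  published tables use 1), computed on exact integer ratios via `Decimal`.
* Quantiles (words/document, documents/patient): linear-interpolation
  quartiles (`numpy.percentile`), since no quantile rule is fixed by
  convention for these tables.
* Ranking ties: lexicographic on the display surface. Largest-remainder
  apportionment breaks ties by remainder then category name. All random
  draws flow from one `random.Random(seed)`; no global state.
* Degenerate inputs: an empty lexicon, an empty map table, an unknown
  relationship label, a decision for an unknown candidate, and an unmapped
  entry without a category are errors, not warnings.

## Known limitations

* The expert steps (clinical-relevance review, the mapping act itself) are
  modeled as data — review sheets and map tables read back in — never
  automated beyond direct lexical matching.
* The character-removal share of cleaning (~11% on defaults) is an
  observation about a given corpus, not a target; it varies with the
  duplicate rate and seed.
* Patients seen in several departments are counted once in the overall
  patients row and once per department column; both numbers are stored
  because the convention differs between reports.
* Mixed-script terms are classed as local-language by the ≥1-character
  rule; a different mixed-script rule would shift the English/Thai split
  on real data.
* No semantic deduplication of near-synonymous candidates, no ontology
  graph reasoning, no postcoordination expression building.
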