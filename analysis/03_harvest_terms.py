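"""Tokenize the cleaned corpus, build candidate N-grams, select interface
terms, and report corpus characteristics.

Reads results/corpus_clean.jsonl (from 02) and the study lexicon; writes the
candidate/review sheet and a corpus-characteristics table under results/.
The desk-scale selection thresholds are the study design's (top 70% of each
rank stratum, or absolute frequency >= 30).
"""

import argparse
import json
import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from importlib import import_module

load_study_lexicon = import_module("02_preprocess_corpus").load_study_lexicon

from uit.corpus import compute_corpus_stats, read_corpus
from uit.harvest import SelectionConfig, export_review_sheet, harvest_and_select
from uit.tokenize import tokenize_corpus


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", default="results/study")
    parser.add_argument("--corpus", default="results/corpus_clean.jsonl")
    parser.add_argument("--frequency-cut", type=int, default=30)
    parser.add_argument("--out", default="results")
    args = parser.parse_args()

    corpus = read_corpus(args.corpus)
    lexicon = load_study_lexicon(args.study)
    doc_tokens = tokenize_corpus(corpus, lexicon)

    stats = compute_corpus_stats(corpus, [dt.flat_surfaces() for dt in doc_tokens])
    rows = {}
    for dept, s in [*stats.per_department.items(), ("Total", stats.overall)]:
        rows[dept] = {
            "n_documents": s.n_documents,
            "n_patients": s.n_patients,
            "total_words": s.total_words,
            "continuous_script_words_pct": s.total_continuous_pct,
            "words_per_doc_median": s.words_per_doc_median,
        }
        print(
            f"{dept}: {s.n_documents} docs, {s.total_words} words, "
            f"{s.total_continuous_pct:.2f}% continuous script, "
            f"median {s.words_per_doc_median:.0f} words/doc"
        )
    with open(os.path.join(args.out, "corpus_stats.json"), "w") as fh:
        json.dump(rows, fh, indent=1)
        fh.write("\n")

    config = SelectionConfig(frequency_cut=args.frequency_cut)
    candidates = harvest_and_select(doc_tokens, config)
    export_review_sheet(candidates, os.path.join(args.out, "candidates.csv"))
    n_kept = sum(1 for c in candidates if c.filtered_reason is None)
    n_selected = sum(1 for c in candidates if c.selected)
    print(
        f"{len(candidates)} candidate N-grams, {n_kept} after syntactic filtering, "
        f"{n_selected} selected (top 70% of rank stratum or frequency >= "
        f"{args.frequency_cut}); expert review sheet: results/candidates.csv"
    )


if __name__ == "__main__":
    main()
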