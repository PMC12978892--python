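"""Clean the raw corpus: harvest abbreviations, normalize, deduplicate
repeated visit sentences, spell-check.

Reads results/study/ (from 01), writes the cleaned corpus, the abbreviation
candidate sheet, and a cleaning report under results/.
"""

import argparse
import dataclasses
import json
import os

from uit.corpus import read_corpus, write_corpus
from uit.lexicon import build_lexicon, harvest_abbreviations, write_abbreviation_sheet
from uit.preprocess import run_preprocess

SOURCE_TAGS = (
    "wordnet_en",
    "wordnet_local",
    "concept_descriptions",
    "drug_db",
    "abbreviations",
)


def load_study_lexicon(study_dir):
    return build_lexicon(
        [(os.path.join(study_dir, "lexicon", f"{t}.txt"), t) for t in SOURCE_TAGS]
    )


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", default="results/study")
    parser.add_argument("--out", default="results")
    args = parser.parse_args()

    corpus = read_corpus(os.path.join(args.study, "corpus.jsonl"))
    lexicon = load_study_lexicon(args.study)

    # capitals only survive in the raw text, so abbreviations come first
    abbrevs = harvest_abbreviations(corpus)
    write_abbreviation_sheet(abbrevs, os.path.join(args.out, "abbreviation_candidates.csv"))
    print(f"abbreviation candidates (>=2 capitals, >100 occurrences): {len(abbrevs)}")
    for c in abbrevs:
        print(f"  {c.surface}: {c.corpus_frequency}")

    cleaned, report = run_preprocess(corpus, lexicon)
    write_corpus(cleaned, os.path.join(args.out, "corpus_clean.jsonl"))
    payload = dataclasses.asdict(report)
    payload["removal_fraction"] = report.removal_fraction
    with open(os.path.join(args.out, "preprocess_report.json"), "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
    print(
        f"cleaning removed {100 * report.removal_fraction:.2f}% of characters "
        f"({report.duplicates_removed} repeated visit sentences, "
        f"{report.corrections_applied} spelling corrections)"
    )


if __name__ == "__main__":
    main()
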