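"""Generate the seeded synthetic study that stands in for the hospital EMR.

Writes the raw corpus (with injected visit duplicates and misspellings), its
noise-free twin, the five lexicon source word lists, the RF2-style concept
catalog, the gold map table, and the generator bookkeeping to
results/study/.
"""

import argparse

from uit.synthdata import StudyDesign, make_study, write_study


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", default="results/study")
    args = parser.parse_args()

    design = StudyDesign(seed=args.seed)
    study = make_study(design)
    write_study(study, args.out)

    n_thai = sum(1 for p in study.planted_terms if p.language == "thai")
    print(f"wrote study to {args.out}")
    print(
        f"  {len(study.corpus)} documents, "
        f"{len(study.planted_terms)} planted terms "
        f"({n_thai} continuous-script / {len(study.planted_terms) - n_thai} Latin)"
    )
    print(
        f"  {len(study.gold_map)} gold map entries, "
        f"{len(study.catalog.concepts)} concepts, "
        f"{study.bookkeeping['duplicates_inserted']} duplicate sentences injected, "
        f"{study.bookkeeping['misspelled_occurrences']} misspellings injected"
    )


if __name__ == "__main__":
    main()
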