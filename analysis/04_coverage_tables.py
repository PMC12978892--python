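"""Coverage analysis: the gold map table of the synthetic study and the
published-table arithmetic.

Produces the equivalence-by-language concept-coverage table, term coverage
by direct lexical match, the one-to-one / one-to-many accounting, and the
unmapped-category breakdown, writing rendered tables under results/.
"""

import argparse
import os

from uit.coverage import full_report, render_report
from uit.mapping import load_concept_catalog, load_map_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", default="results/study")
    parser.add_argument("--out", default="results")
    args = parser.parse_args()

    table = load_map_table(os.path.join(args.study, "gold_map.csv"))
    catalog = load_concept_catalog(os.path.join(args.study, "descriptions.tsv"))
    report = full_report(table, catalog)

    text = render_report(report, "text")
    print(text)
    with open(os.path.join(args.out, "coverage_report.txt"), "w") as fh:
        fh.write(text)
    with open(os.path.join(args.out, "coverage_report.md"), "w") as fh:
        fh.write(render_report(report, "markdown"))
    with open(os.path.join(args.out, "coverage_report.csv"), "w") as fh:
        fh.write(render_report(report, "delimited"))
    print("wrote coverage_report.{txt,md,csv} under", args.out)


if __name__ == "__main__":
    main()
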