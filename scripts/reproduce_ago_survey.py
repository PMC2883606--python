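"""Reproduce the Argonaute-library telomeric siRNA survey on real data.

The survey counted 133 small RNAs carrying at least 12 nt of perfect
telomeric repeat across four Argonaute-IP libraries (AGO1, AGO2, AGO4,
AGO5; GEO accession GSE10036).  This script is NOT run by the test
suite: it requires the library FASTA files to be downloaded first
(e.g. from GEO), one file per library, and reports the telomeric hit
count per library and in total.  The exact total can shift with
preprocessing choices (duplicate collapsing in particular), so treat
agreement within ~10% as a successful reproduction.

Usage:
    python scripts/reproduce_ago_survey.py AGO1.fasta AGO2.fasta \
        AGO4.fasta AGO5.fasta [--min-homology 12] [--collapse-identical]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from teloepi.io import read_smallrna
from teloepi.repeat_scan import classify_sirnas, homology_distribution, library_crosstab


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("fastas", nargs="+", type=Path,
                        help="One small-RNA FASTA/FASTQ per AGO library")
    parser.add_argument("--min-homology", type=int, default=12)
    parser.add_argument("--collapse-identical", action="store_true")
    parser.add_argument("--expected-total", type=int, default=133)
    args = parser.parse_args()

    reads = []
    for path in args.fastas:
        reads.extend(read_smallrna(path))
    hits = classify_sirnas(
        reads, args.min_homology, collapse_identical=args.collapse_identical
    )
    print(library_crosstab(hits).to_string())
    print()
    print(homology_distribution(hits).to_string(index=False))
    total = len(hits)
    lo, hi = 0.9 * args.expected_total, 1.1 * args.expected_total
    verdict = "within" if lo <= total <= hi else "outside"
    print(f"\ntotal telomeric siRNAs: {total} "
          f"({verdict} 10% of expected {args.expected_total})")


if __name__ == "__main__":
    main()
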