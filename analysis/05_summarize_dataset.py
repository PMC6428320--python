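#!/usr/bin/env python
"""Dataset-level accounting: share of OTU diversity and of read volume
attributable to barcoded morphospecies, and per-size-fraction clade
composition.

Reads results/survey/ and results/assignment/ and writes summary.json
and clade_share_by_fraction.tsv under results/summary/.
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from foramtax.assignment import summarize_dataset
from foramtax.sequence_io import read_counts_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--survey", type=Path, default=Path("results/survey"))
    ap.add_argument("--assignment", type=Path, default=Path("results/assignment"))
    ap.add_argument("--out", type=Path, default=Path("results/summary"))
    args = ap.parse_args()

    assignments = pd.read_csv(args.assignment / "assignments.tsv", sep="\t", index_col=0)
    reads = read_counts_table(args.survey / "otu_reads.tsv")
    summary = summarize_dataset(assignments, reads)

    args.out.mkdir(parents=True, exist_ok=True)
    shares = summary.pop("clade_share_by_fraction")
    shares.to_csv(args.out / "clade_share_by_fraction.tsv", sep="\t")
    (args.out / "summary.json").write_text(json.dumps(summary, indent=1))

    print(f"{summary['n_otus']} OTUs: "
          f"{summary['pct_otus_attributed']:.1f}% of OTU diversity and "
          f"{summary['pct_reads_attributed']:.1f}% of read volume attributed "
          "to barcoded morphospecies")
    print("clade share per size fraction (% of reads):")
    print(shares.round(1).to_string())
    print(f"wrote {args.out}/")


if __name__ == "__main__":
    main()
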