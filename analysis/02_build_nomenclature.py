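#!/usr/bin/env python
"""Call basetypes (>= 3 observations, exact patterns) and assemble
basegroups (specimen co-occurrence components) from the survey written
by 01_simulate_survey.py.

Writes basetypes.fasta / basetypes.tsv / basegroups.tsv and the report
of discarded singleton/doubleton patterns under results/nomenclature/.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from foramtax.nomenclature import (
    assemble_basegroups,
    call_basetypes,
    write_basegroups,
    write_basetypes,
)
from foramtax.sequence_io import read_reference_fasta


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--survey", type=Path, default=Path("results/survey"))
    ap.add_argument("--out", type=Path, default=Path("results/nomenclature"))
    ap.add_argument("--min-obs", type=int, default=3)
    ap.add_argument("--count-unit", choices=["sequences", "specimens"],
                    default="sequences")
    args = ap.parse_args()

    records = read_reference_fasta(
        args.survey / "reference.fasta", args.survey / "metadata.tsv"
    )
    basetypes, discarded = call_basetypes(
        records, min_obs=args.min_obs, count_unit=args.count_unit
    )
    basegroups = assemble_basegroups(basetypes)

    args.out.mkdir(parents=True, exist_ok=True)
    write_basetypes(basetypes, args.out / "basetypes.fasta", args.out / "basetypes.tsv")
    write_basegroups(basegroups, args.out / "basegroups.tsv")
    discarded.to_csv(args.out / "discarded_patterns.tsv", sep="\t", index=False)

    print(f"{len(records)} curated reads -> {len(basetypes)} basetypes "
          f"in {len(basegroups)} basegroups")
    print(f"{len(discarded)} patterns below the >= {args.min_obs}-observation "
          "filter (putative sequencing errors)")
    print(f"wrote {args.out}/")


if __name__ == "__main__":
    main()
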