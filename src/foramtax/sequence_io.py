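"""Reading/writing barcode data and marker-region handling.

Sequences travel as :class:`SequenceRecord` objects joining a FASTA
entry to its specimen metadata (morphospecies, clade, station,
sequencing type). Alignments are ordered ``{label: sequence}`` mappings
of uniform width; marker sub-regions are addressed by 0-based,
half-open column intervals on such a master alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "CLADES",
    "MIN_NOMENCLATURE_LENGTH",
    "SequenceRecord",
    "MarkerRegion",
    "read_fasta",
    "write_fasta",
    "read_reference_fasta",
    "write_reference_set",
    "extract_marker",
    "read_counts_table",
]

#: The six major clade bins used for step-1 assignment of environmental OTUs.
CLADES = (
    "Spinose",
    "Non-Spinose",
    "Microperforates",
    "Basal",
    "Monolamellar",
    "Benthic",
)

#: Sequences shorter than this many unambiguous sites are kept for
#: genotyping but excluded from nomenclature construction.
MIN_NOMENCLATURE_LENGTH = 200

IUPAC = set("ACGTURYSWKMBDHVN-")

METADATA_COLUMNS = [
    "seq_id",
    "specimen_id",
    "morphospecies",
    "clade",
    "station",
    "sequencing_type",
]


@dataclass
class SequenceRecord:
    """One barcode read with its specimen provenance."""

    seq_id: str
    seq: str
    specimen_id: str
    morphospecies: str = "unknown"
    clade: str = "unknown"
    station: str = "unknown"
    sequencing_type: str = "direct"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"{self.seq_id}: empty sequence")
        bad = set(self.seq.upper()) - IUPAC
        if bad:
            raise ValueError(f"{self.seq_id}: non-IUPAC symbols {sorted(bad)}")
        if self.sequencing_type not in ("direct", "clone"):
            raise ValueError(
                f"{self.seq_id}: sequencing_type must be direct|clone, "
                f"got {self.sequencing_type!r}"
            )

    @property
    def ungapped(self) -> str:
        return self.seq.replace("-", "").upper()

    @property
    def length_ok(self) -> bool:
        """True when long enough (>=200 unambiguous sites) for nomenclature."""
        n = sum(1 for ch in self.ungapped if ch in "ACGTU")
        return n >= MIN_NOMENCLATURE_LENGTH


@dataclass(frozen=True)
class MarkerRegion:
    """A named column interval (0-based, half-open) on a master alignment."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = sequences.items() if isinstance(sequences, dict) else sequences
    records = [
        _BioSeqRecord(Seq(s), id=name, description="") for name, s in items
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(
    fasta_path: str | Path, metadata_path: str | Path
) -> list[SequenceRecord]:
    """Join a reference FASTA with its TSV metadata table.

    Every FASTA id must appear in the metadata (hard error listing the
    offenders); metadata rows without a FASTA entry are ignored with a
    warning. Unknown morphospecies/clade values are allowed and kept as
    the literal string ``"unknown"``.
    """
    seqs = read_fasta(fasta_path)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("unknown")
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    if meta["seq_id"].duplicated().any():
        dups = meta.loc[meta["seq_id"].duplicated(), "seq_id"].tolist()
        raise ValueError(f"duplicate seq_id in metadata: {dups}")
    meta_ids = set(meta["seq_id"])
    orphans = sorted(set(seqs) - meta_ids)
    if orphans:
        raise ValueError(f"FASTA ids absent from metadata: {orphans}")
    extra = meta_ids - set(seqs)
    if extra:
        warnings.warn(
            f"{len(extra)} metadata rows have no FASTA entry and were ignored",
            stacklevel=2,
        )
    by_id = meta.set_index("seq_id")
    records = []
    for seq_id, seq in seqs.items():
        row = by_id.loc[seq_id]
        records.append(
            SequenceRecord(
                seq_id=seq_id,
                seq=seq,
                specimen_id=row["specimen_id"],
                morphospecies=row["morphospecies"],
                clade=row["clade"],
                station=row["station"],
                sequencing_type=row["sequencing_type"],
            )
        )
    return records


def write_reference_set(
    records: Iterable[SequenceRecord],
    fasta_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write records back to FASTA + TSV (lossless round-trip)."""
    records = list(records)
    write_fasta([(r.seq_id, r.seq) for r in records], fasta_path)
    rows = [
        {
            "seq_id": r.seq_id,
            "specimen_id": r.specimen_id,
            "morphospecies": r.morphospecies,
            "clade": r.clade,
            "station": r.station,
            "sequencing_type": r.sequencing_type,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        metadata_path, sep="\t", index=False
    )


def extract_marker(
    alignment: dict[str, str], region: MarkerRegion
) -> tuple[dict[str, str], list[str]]:
    """Restrict an alignment to a marker's columns.

    Returns the sliced alignment (row order preserved) and the list of
    labels whose slice is entirely gaps/missing.

    Raises
    ------
    ValueError
        On ragged input, zero-width regions, or out-of-bounds intervals.
    """
    widths = {len(s) for s in alignment.values()}
    if len(widths) > 1:
        raise ValueError("alignment rows have unequal widths")
    if region.width == 0:
        raise ValueError(f"marker {region.name}: zero-width region")
    width = widths.pop() if widths else 0
    if region.end > width:
        raise ValueError(
            f"marker {region.name}: interval [{region.start}, {region.end}) "
            f"out of bounds for alignment width {width}"
        )
    sliced = {k: s[region.start : region.end] for k, s in alignment.items()}
    all_gap = [k for k, s in sliced.items() if not set(s.upper()) & set("ACGTU")]
    return sliced, all_gap


def read_counts_table(path: str | Path) -> pd.DataFrame:
    """Read an OTU read-count matrix (rows = OTU ids, columns = sample|fraction)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError("negative read counts")
    return df
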