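"""Two-step annotation of environmental metabarcode OTUs.

Step 1 assigns each OTU to one of the six major foraminifera clades by
its nearest reference under the Kimura K80 distance (with the margin to
the nearest other-clade reference reported, so ambiguous calls stay
visible). Step 2 places the OTU's nearest-reference distance inside
the empirical rank bands of the reference taxonomy — intra-basegroup up
to inter-clade — and classifies its novelty: a distance compatible with
intra- or inter-basegroup variability means the OTU adds no diversity
(``known_basegroup``); larger distances suggest an unsampled genotype,
lineage, or something beyond the known morphospecies-level variability.

Band boundaries use the observed maximum of each band (conservative
against inventing novelty). Classification uses the K80 distance;
patristic distances, when supplied, are reported as a concordance
column only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .distances import (
    DEFAULT_MIN_SITES,
    SiteCounts,
    kimura_k80,
    site_counts,
    encode,
)
from .sequence_io import MarkerRegion

__all__ = [
    "RANK_LEVELS",
    "NOVELTY_CLASSES",
    "OtuRecord",
    "RankBands",
    "AssignmentResult",
    "pair_rank_level",
    "assign_clade",
    "build_rank_bands",
    "classify_novelty",
    "flag_chimera",
    "assign_all",
    "summarize_dataset",
]

#: Taxonomic levels a reference pair can share, finest to coarsest.
RANK_LEVELS = (
    "intra_basegroup",
    "inter_basegroup",
    "inter_genotype",
    "inter_lineage",
    "congeneric_morphospecies",
    "inter_clade",
)

NOVELTY_CLASSES = (
    "known_basegroup",
    "new_genotype",
    "new_lineage",
    "exceeds_morphospecies",
    "benthic_affinity",
    "chimera_flag",
)

#: Novelty classes that tie an OTU to a barcoded morphospecies.
ATTRIBUTED_CLASSES = frozenset(
    {"known_basegroup", "new_genotype", "new_lineage"}
)


@dataclass
class OtuRecord:
    otu_id: str
    rep_seq: str
    marker: str = "FORAM_37F"
    reads: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.reads.values()):
            raise ValueError(f"{self.otu_id}: negative read counts")


@dataclass
class RankBands:
    """Empirical distance distribution per shared-rank level.

    ``stats`` maps level -> dict(n, min, q1, median, q3, max); levels
    with fewer than ``min_pairs`` contributing pairs are absent
    (classification falls through to the next available level).
    """

    stats: dict[str, dict[str, float]]
    metric: str = "k80"

    def available(self, level: str) -> bool:
        return level in self.stats

    def upper(self, level: str) -> float:
        return self.stats[level]["max"]


@dataclass
class AssignmentResult:
    otu_id: str
    clade: str
    nearest_ref: str
    distance: float
    margin: float
    novelty: str
    motu_labels: dict[str, str] = field(default_factory=dict)
    d_patristic: float | None = None


def pair_rank_level(tax_a: Mapping[str, str], tax_b: Mapping[str, str]) -> str:
    """Most-recent-shared-label rank of a reference pair.

    Each taxonomy mapping needs keys clade, morphospecies, lvl1, lvl2,
    lvl3. Every pair contributes to exactly one level.
    """
    if tax_a["clade"] != tax_b["clade"]:
        return "inter_clade"
    if tax_a["morphospecies"] != tax_b["morphospecies"]:
        return "congeneric_morphospecies"
    if tax_a["lvl1"] != tax_b["lvl1"]:
        return "inter_lineage"
    if tax_a["lvl2"] != tax_b["lvl2"]:
        return "inter_genotype"
    if tax_a["lvl3"] != tax_b["lvl3"]:
        return "inter_basegroup"
    return "intra_basegroup"


def _pairwise_to_refs(
    otu_seq: str,
    ref_alignment: Mapping[str, str],
    min_sites: int,
) -> pd.Series:
    enc_otu = encode(otu_seq)
    out = {}
    for ref_id, ref_seq in ref_alignment.items():
        c = site_counts(enc_otu, encode(ref_seq))
        out[ref_id] = kimura_k80(c, min_sites=min_sites)
    return pd.Series(out, dtype=float)


def assign_clade(
    otu_seq: str,
    ref_alignment: Mapping[str, str],
    ref_clades: Mapping[str, str],
    marker: MarkerRegion | None = None,
    min_sites: int = DEFAULT_MIN_SITES,
) -> tuple[str, str, float, float]:
    """Step 1: clade of the nearest reference under K80.

    The OTU must already be aligned to the reference marker columns.
    Returns (clade, nearest_ref, distance, margin) where margin is the
    gap to the nearest reference of any *other* clade (inf when every
    reference belongs to one clade). An OTU whose comparisons are all
    masked returns clade ``"unassignable"``.
    """
    if marker is not None:
        otu_seq = otu_seq[marker.start : marker.end]
        ref_alignment = {
            k: v[marker.start : marker.end] for k, v in ref_alignment.items()
        }
    d = _pairwise_to_refs(otu_seq, ref_alignment, min_sites).dropna()
    if d.empty:
        return "unassignable", "", float("nan"), float("nan")
    nearest = d.idxmin()
    clade = ref_clades[nearest]
    other = d[[ref_clades[r] != clade for r in d.index]]
    margin = float(other.min() - d[nearest]) if not other.empty else float("inf")
    return clade, str(nearest), float(d[nearest]), margin


def build_rank_bands(
    ref_alignment: Mapping[str, str],
    taxonomy: pd.DataFrame,
    clades: Mapping[str, str],
    marker: MarkerRegion | None = None,
    metric_matrix: "pd.DataFrame | None" = None,
    min_sites: int = DEFAULT_MIN_SITES,
    min_pairs: int = 2,
) -> RankBands:
    """Empirical distance bands per shared-rank level over reference pairs.

    ``taxonomy`` is the consensus MOTU table (index basetype/reference
    id, columns morphospecies..lvl3); ``clades`` adds the clade of each
    reference. Pass ``metric_matrix`` (a square DataFrame, e.g.
    patristic distances) to band an alternative metric instead of
    recomputing K80 from the alignment.
    """
    ids = [i for i in taxonomy.index if i in ref_alignment]
    if marker is not None and metric_matrix is None:
        ref_alignment = {
            k: v[marker.start : marker.end] for k, v in ref_alignment.items()
        }
    tax = {
        i: {
            "clade": clades[i],
            **taxonomy.loc[i, ["morphospecies", "lvl1", "lvl2", "lvl3"]].to_dict(),
        }
        for i in ids
    }
    per_level: dict[str, list[float]] = {lvl: [] for lvl in RANK_LEVELS}
    enc = {i: encode(ref_alignment[i]) for i in ids} if metric_matrix is None else {}
    for a_pos, a in enumerate(ids):
        for b in ids[a_pos + 1 :]:
            if metric_matrix is not None:
                d = float(metric_matrix.loc[a, b])
            else:
                d = kimura_k80(site_counts(enc[a], enc[b]), min_sites=min_sites)
            if np.isnan(d):
                continue
            per_level[pair_rank_level(tax[a], tax[b])].append(d)
    stats = {}
    for lvl, vals in per_level.items():
        if len(vals) < min_pairs:
            continue
        arr = np.asarray(vals)
        stats[lvl] = {
            "n": float(arr.size),
            "min": float(arr.min()),
            "q1": float(np.quantile(arr, 0.25)),
            "median": float(np.quantile(arr, 0.5)),
            "q3": float(np.quantile(arr, 0.75)),
            "max": float(arr.max()),
        }
    metric = "k80" if metric_matrix is None else "patristic"
    return RankBands(stats=stats, metric=metric)


def classify_novelty(distance: float, bands: RankBands) -> str:
    """Step 2: place a nearest-reference distance in the rank bands.

    Distances up to the inter-basegroup ceiling are compatible with the
    variability already captured by the reference (no new diversity);
    beyond that the OTU represents an unsampled genotype, lineage, or —
    above the morphospecies-level (inter-lineage) ceiling — something
    exceeding the known congeneric structure. Unavailable bands fall
    through to the next level up (conservative, with a warning).
    """
    if np.isnan(distance):
        raise ValueError("cannot classify a masked distance")
    ladder = [
        ("inter_basegroup", "known_basegroup"),
        ("inter_genotype", "new_genotype"),
        ("inter_lineage", "new_lineage"),
    ]
    # intra_basegroup can substitute when inter_basegroup is missing.
    if not bands.available("inter_basegroup") and bands.available("intra_basegroup"):
        ladder[0] = ("intra_basegroup", "known_basegroup")
    for level, klass in ladder:
        if not bands.available(level):
            warnings.warn(
                f"band {level!r} unavailable (<2 pairs); falling through to a "
                "higher novelty class",
                stacklevel=2,
            )
            continue
        if distance <= bands.upper(level):
            return klass
    return "exceeds_morphospecies"


def flag_chimera(
    otu_seq: str,
    ref_alignment: Mapping[str, str],
    ref_clades: Mapping[str, str],
    margin_threshold: float = 0.02,
    min_sites: int = DEFAULT_MIN_SITES,
    min_half_length: int = 100,
) -> bool:
    """Half-split heuristic: halves assigning to different clades with
    confident margins flag a likely PCR chimera. Off by default in the
    pipeline; the call this emulates was a manual inspection."""
    if len(otu_seq) < 2 * min_half_length:
        return False
    cut = len(otu_seq) // 2
    halves = (otu_seq[:cut], otu_seq[cut:])
    calls = []
    for half, refs in zip(
        halves,
        (
            {k: v[:cut] for k, v in ref_alignment.items()},
            {k: v[cut:] for k, v in ref_alignment.items()},
        ),
    ):
        clade, _, _, margin = assign_clade(
            half, refs, ref_clades, min_sites=min(min_sites, min_half_length)
        )
        calls.append((clade, margin))
    (c1, m1), (c2, m2) = calls
    if "unassignable" in (c1, c2) or c1 == c2:
        return False
    return m1 >= margin_threshold and m2 >= margin_threshold


def assign_all(
    otus: Mapping[str, str],
    ref_alignment: Mapping[str, str],
    ref_clades: Mapping[str, str],
    taxonomy: pd.DataFrame,
    bands: RankBands,
    novelty_clades: Iterable[str] | None = None,
    benthic_clades: Iterable[str] = ("Benthic",),
    check_chimeras: bool = False,
    min_sites: int = DEFAULT_MIN_SITES,
) -> pd.DataFrame:
    """Run both annotation steps over a set of OTUs.

    ``novelty_clades`` restricts step 2 to the named clades (None = all
    non-benthic); OTUs nearest a benthic reference get
    ``benthic_affinity`` and skip step 2.

    Returns a DataFrame (index otu_id) with columns clade, nearest_ref,
    d_k80, margin, novelty and the MOTU labels of the nearest reference
    where the OTU is attributable.
    """
    benthic = set(benthic_clades)
    rows = []
    for otu_id, seq in otus.items():
        clade, nearest, d, margin = assign_clade(
            seq, ref_alignment, ref_clades, min_sites=min_sites
        )
        if check_chimeras and flag_chimera(seq, ref_alignment, ref_clades):
            novelty = "chimera_flag"
        elif clade == "unassignable":
            novelty = "unassignable"
        elif clade in benthic:
            novelty = "benthic_affinity"
        elif novelty_clades is not None and clade not in set(novelty_clades):
            novelty = "out_of_scope"
        else:
            novelty = classify_novelty(d, bands)
        row = {
            "otu_id": otu_id,
            "clade": clade,
            "nearest_ref": nearest,
            "d_k80": d,
            "margin": margin,
            "novelty": novelty,
        }
        if novelty in ATTRIBUTED_CLASSES and nearest in taxonomy.index:
            for col in ("morphospecies", "lvl1", "lvl2", "lvl3"):
                row[f"motu_{col}"] = taxonomy.loc[nearest, col]
        rows.append(row)
    return pd.DataFrame(rows).set_index("otu_id")


def summarize_dataset(
    assignments: pd.DataFrame, reads: pd.DataFrame
) -> dict[str, object]:
    """Dataset-level accounting of assigned diversity and read volume.

    Returns percentages of OTUs and reads attributed to barcoded
    morphospecies (chimera-flagged OTUs excluded from the totals) and,
    per size fraction (the part of each column label after ``|``), the
    relative read share of each clade.

    Raises
    ------
    ValueError
        If the dataset carries zero reads in total.
    """
    if reads.values.sum() == 0:
        raise ValueError("zero-read dataset")
    merged = assignments.join(reads.sum(axis=1).rename("total_reads"), how="left")
    merged["total_reads"] = merged["total_reads"].fillna(0)
    kept = merged[merged["novelty"] != "chimera_flag"]
    attributed = kept["novelty"].isin(ATTRIBUTED_CLASSES)
    total_reads = kept["total_reads"].sum()
    pct_otus = 100.0 * attributed.sum() / len(kept) if len(kept) else float("nan")
    pct_reads = (
        100.0 * kept.loc[attributed, "total_reads"].sum() / total_reads
        if total_reads
        else float("nan")
    )

    fraction_of = {c: c.split("|")[-1] for c in reads.columns}
    kept_reads = reads.loc[reads.index.intersection(kept.index)]
    by_clade = kept_reads.groupby(
        kept.loc[kept_reads.index, "clade"]
    ).sum()
    by_fraction = by_clade.T.groupby(fraction_of).sum()  # fraction x clade
    shares = by_fraction.div(by_fraction.sum(axis=1), axis=0) * 100.0

    return {
        "n_otus": int(len(kept)),
        "pct_otus_attributed": float(pct_otus),
        "pct_reads_attributed": float(pct_reads),
        "clade_share_by_fraction": shares,
    }
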