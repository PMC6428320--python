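"""End-to-end orchestration: reads -> nomenclature -> MOTUs -> OTU annotation.

The reference half mirrors the barcoding workflow: call basetypes from
the curated reads, assemble basegroups from specimen co-occurrence,
then — separately within each clade, whose evolutionary rates differ —
run the barcode-gap delimitation (initial and recursive) and the
branch-rate delimitation on a rooted NJ tree, invalidate partitions
that split basegroups or lump morphospecies, and take the consensus
MOTU hierarchy. The environmental half builds rank bands from the
reference taxonomy and annotates OTUs in two steps.

Sequences are assumed substitution-aligned (uniform length after gap
stripping), which holds for the synthetic surveys; real data must be
aligned externally first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import delimitation as dl
from .assignment import RankBands, assign_all, build_rank_bands, summarize_dataset
from .distances import distance_matrix
from .nomenclature import (
    Basegroup,
    Basetype,
    assemble_basegroups,
    call_basetypes,
)
from .phylogeny import nj_tree, patristic_distances, root_with_outgroup
from .sequence_io import MarkerRegion, SequenceRecord
from .synthetic_data import SimulationConfig, SyntheticTruth

__all__ = ["TaxonomyResult", "build_taxonomy", "annotate_otus", "run_synthetic_survey"]

OUTGROUP_LABEL = "OUTGROUP"


@dataclass
class TaxonomyResult:
    basetypes: list[Basetype]
    basegroups: list[Basegroup]
    discarded: pd.DataFrame
    taxonomy: pd.DataFrame
    clades: dict[str, str]
    partitions: dict[str, list[dl.Partition]] = field(default_factory=dict)

    @property
    def alignment(self) -> dict[str, str]:
        return {bt.basetype_id: bt.pattern for bt in self.basetypes}

    def audit(self) -> list[dict[str, object]]:
        """Flat bookkeeping of every proposed partition and its fate."""
        out = []
        for clade, parts in self.partitions.items():
            for p in parts:
                out.append(
                    {
                        "clade": clade,
                        "method": p.method,
                        "prior": p.prior,
                        "n_groups": p.n_groups,
                        "valid": p.valid,
                        "violations": [
                            {"kind": kind, "members": list(members)}
                            for kind, members in p.violations
                        ],
                    }
                )
        return out


def build_taxonomy(
    records: list[SequenceRecord],
    outgroup_seq: str | None = None,
    marker: MarkerRegion | None = None,
    min_obs: int = 3,
    min_sites: int = 100,
    seed: int = 0,
) -> TaxonomyResult:
    """Run the full reference side of the pipeline.

    ``outgroup_seq`` (a distant benthic reference, aligned to the same
    columns) enables the branch-rate delimitation, which needs a rooted
    tree; without it only the barcode-gap partitions are used.
    """
    basetypes, discarded = call_basetypes(records, marker=marker, min_obs=min_obs)
    basegroups = assemble_basegroups(basetypes)
    morpho_clade = {
        r.morphospecies: r.clade for r in records if r.morphospecies != "unknown"
    }
    clades = {bt.basetype_id: morpho_clade[bt.morphospecies] for bt in basetypes}
    morpho_map = {bt.basetype_id: bt.morphospecies for bt in basetypes}
    alignment = {bt.basetype_id: bt.pattern for bt in basetypes}

    partitions: dict[str, list[dl.Partition]] = {}
    frames = []
    for clade in sorted(set(clades.values())):
        members = sorted(b for b, c in clades.items() if c == clade)
        clade_bgs = [bg for bg in basegroups if bg.basetypes <= set(members)]
        proposed: list[dl.Partition] = []
        if len(members) >= 2:
            dm = distance_matrix(
                {m: alignment[m] for m in members}, model="k80", min_sites=min_sites
            )
            proposed.append(dl.abgd_partition(dm, mode="initial"))
            proposed.append(dl.abgd_partition(dm, mode="recursive"))
            if outgroup_seq is not None and len(members) >= 3:
                dm_og = distance_matrix(
                    {**{m: alignment[m] for m in members}, OUTGROUP_LABEL: outgroup_seq},
                    model="k80",
                    min_sites=min_sites,
                )
                tree = root_with_outgroup(nj_tree(dm_og), OUTGROUP_LABEL)
                proposed.append(dl.ptp_delimit(tree, outgroup=OUTGROUP_LABEL, seed=seed))
        validated = [
            dl.validate_partition(p, clade_bgs, morpho_map) for p in proposed
        ]
        partitions[clade] = validated
        frame = dl.consensus_motus(validated, clade_bgs, morpho_map)
        frame["lvl1"] = clade + "." + frame["lvl1"]
        frame["lvl2"] = clade + "." + frame["lvl2"]
        frames.append(frame)
    taxonomy = pd.concat(frames).sort_index() if frames else pd.DataFrame(
        columns=["morphospecies", "lvl1", "lvl2", "lvl3"]
    )
    return TaxonomyResult(
        basetypes=basetypes,
        basegroups=basegroups,
        discarded=discarded,
        taxonomy=taxonomy,
        clades=clades,
        partitions=partitions,
    )


def annotate_otus(
    otus: dict[str, str],
    result: TaxonomyResult,
    marker: MarkerRegion,
    min_sites: int = 100,
    check_chimeras: bool = False,
) -> tuple[pd.DataFrame, RankBands]:
    """Annotate environmental OTUs against a built reference taxonomy.

    OTU sequences must cover exactly the marker's columns; references
    are sliced to the same interval.
    """
    ref_marker = {
        k: v[marker.start : marker.end] for k, v in result.alignment.items()
    }
    bands = build_rank_bands(
        ref_marker, result.taxonomy, result.clades, min_sites=min_sites
    )
    assignments = assign_all(
        otus,
        ref_marker,
        result.clades,
        result.taxonomy,
        bands,
        check_chimeras=check_chimeras,
        min_sites=min_sites,
    )
    return assignments, bands


def run_synthetic_survey(
    config: SimulationConfig,
) -> dict[str, object]:
    """Simulate one survey and push it through the whole pipeline.

    Returns the truth, the recovered taxonomy, the OTU annotations and
    the dataset summary — the working set for recovery experiments.
    """
    from .synthetic_data import simulate_env_otus, simulate_reference_set

    records, metadata, truth = simulate_reference_set(config)
    otus, reads = simulate_env_otus(config, truth)
    result = build_taxonomy(
        records, outgroup_seq=truth.outgroup_seq, seed=config.seed
    )
    marker = config.marker_regions()[config.env_marker]
    min_sites = min(100, max(30, marker.width // 2))
    assignments, bands = annotate_otus(otus, result, marker, min_sites=min_sites)
    summary = summarize_dataset(assignments, reads)
    return {
        "records": records,
        "metadata": metadata,
        "truth": truth,
        "result": result,
        "otus": otus,
        "reads": reads,
        "assignments": assignments,
        "bands": bands,
        "summary": summary,
    }
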