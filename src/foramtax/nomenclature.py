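"""Basetypes and basegroups: the two lowest tiers of the molecular taxonomy.

A *basetype* is a distinct (exact-match, gap-stripped) sequence pattern
over the marker region observed at least ``min_obs`` times — the
threshold screens out rare sequencing errors, which appear as singleton
or doubleton patterns. A *basegroup* bundles the basetypes that
co-occur within one or more individuals: cloning reveals several
distinct gene copies per specimen (intragenomic rDNA variability), so
basetypes linked through shared specimens belong to one organismal
lineage. Basegroups are the connected components of the bipartite
basetype-specimen graph and form MOTU level 3.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .sequence_io import MarkerRegion, SequenceRecord

__all__ = [
    "Basetype",
    "Basegroup",
    "CurationError",
    "call_basetypes",
    "assemble_basegroups",
    "write_basetypes",
    "write_basegroups",
]


class CurationError(ValueError):
    """Raised when the data contradict the nomenclature's assumptions.

    A retained pattern supported by two morphospecies, or a basegroup
    spanning two morphospecies, indicates an upstream labelling problem
    that must be fixed by manual curation, not silently resolved.
    """


@dataclass
class Basetype:
    basetype_id: str
    pattern: str
    n_obs: int
    specimens: frozenset[str]
    morphospecies: str
    supporting_seq_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")
        if not self.specimens:
            raise ValueError("a basetype needs at least one specimen")


@dataclass
class Basegroup:
    basegroup_id: str
    basetypes: frozenset[str]
    morphospecies: str

    def __post_init__(self) -> None:
        if not self.basetypes:
            raise ValueError("a basegroup needs at least one basetype")


def _pattern(record: SequenceRecord, marker: MarkerRegion | None) -> str:
    seq = record.seq
    if marker is not None:
        seq = seq[marker.start : marker.end]
    return seq.replace("-", "").upper()


def call_basetypes(
    records: Iterable[SequenceRecord],
    marker: MarkerRegion | None = None,
    min_obs: int = 3,
    count_unit: str = "sequences",
) -> tuple[list[Basetype], pd.DataFrame]:
    """Deduplicate marker-region patterns and apply the >=min_obs filter.

    Records that are too short (``length_ok`` False) or lack a known
    morphospecies are excluded up front. Patterns are compared exactly
    after gap stripping; no partial-containment merging.

    Parameters
    ----------
    count_unit:
        ``"sequences"`` (default) counts every read — direct reads and
        clones alike — toward the threshold; ``"specimens"`` counts
        distinct specimens only.

    Returns
    -------
    (basetypes, discarded)
        ``discarded`` is a report of the patterns that failed the
        threshold, with their observation counts.

    Raises
    ------
    CurationError
        If a *retained* pattern is supported by specimens of two
        different morphospecies.
    """
    if count_unit not in ("sequences", "specimens"):
        raise ValueError("count_unit must be 'sequences' or 'specimens'")
    groups: dict[str, list[SequenceRecord]] = defaultdict(list)
    for rec in records:
        if not rec.length_ok or rec.morphospecies == "unknown":
            continue
        groups[_pattern(rec, marker)].append(rec)

    basetypes: list[Basetype] = []
    discarded_rows = []
    # Deterministic ordering: by (morphospecies, pattern).
    ordered = sorted(
        groups.items(), key=lambda kv: (kv[1][0].morphospecies, kv[0])
    )
    idx = 0
    for pattern, recs in ordered:
        if count_unit == "sequences":
            n_obs = len(recs)
        else:
            n_obs = len({r.specimen_id for r in recs})
        if n_obs < min_obs:
            discarded_rows.append(
                {
                    "pattern": pattern,
                    "n_obs": n_obs,
                    "seq_ids": ",".join(r.seq_id for r in recs),
                }
            )
            continue
        morphos = sorted({r.morphospecies for r in recs})
        if len(morphos) > 1:
            raise CurationError(
                f"pattern supported by {len(recs)} reads spans morphospecies "
                f"{morphos}; relabel upstream (seq ids: "
                f"{[r.seq_id for r in recs]})"
            )
        idx += 1
        basetypes.append(
            Basetype(
                basetype_id=f"BT{idx:04d}",
                pattern=pattern,
                n_obs=n_obs,
                specimens=frozenset(r.specimen_id for r in recs),
                morphospecies=morphos[0],
                supporting_seq_ids=tuple(sorted(r.seq_id for r in recs)),
            )
        )
    discarded = pd.DataFrame(
        discarded_rows, columns=["pattern", "n_obs", "seq_ids"]
    )
    return basetypes, discarded


def assemble_basegroups(
    basetypes: Iterable[Basetype],
    specimen_contents: Mapping[str, Iterable[str]] | None = None,
) -> list[Basegroup]:
    """Group basetypes into basegroups by transitive specimen co-occurrence.

    Basegroups are the connected components of the bipartite graph
    linking basetypes to the specimens that carry them, restricted to
    the basetype nodes. By default the specimen sets recorded on the
    basetypes are used; an explicit ``specimen_contents`` map
    (specimen -> basetype ids observed) overrides them.

    Raises
    ------
    CurationError
        If a component mixes morphospecies (listing the specimens that
        bridge them).
    """
    basetypes = list(basetypes)
    by_id = {bt.basetype_id: bt for bt in basetypes}
    if len(by_id) != len(basetypes):
        raise ValueError("duplicate basetype ids")

    g = nx.Graph()
    for bt in basetypes:
        g.add_node(("bt", bt.basetype_id))
    if specimen_contents is None:
        for bt in basetypes:
            for sp in bt.specimens:
                g.add_edge(("bt", bt.basetype_id), ("sp", sp))
    else:
        for sp, bts in specimen_contents.items():
            for b in bts:
                if b in by_id:
                    g.add_edge(("bt", b), ("sp", sp))

    components = []
    for comp in nx.connected_components(g):
        members = sorted(n[1] for n in comp if n[0] == "bt")
        if members:
            components.append((members, sorted(n[1] for n in comp if n[0] == "sp")))
    components.sort(key=lambda c: c[0][0])

    basegroups = []
    for i, (members, specimens) in enumerate(components, start=1):
        morphos = sorted({by_id[m].morphospecies for m in members})
        if len(morphos) > 1:
            raise CurationError(
                f"basegroup component {members} spans morphospecies {morphos} "
                f"via specimens {specimens}"
            )
        basegroups.append(
            Basegroup(
                basegroup_id=f"BG{i:04d}",
                basetypes=frozenset(members),
                morphospecies=morphos[0],
            )
        )
    return basegroups


def write_basetypes(
    basetypes: Iterable[Basetype], fasta_path: str | Path, tsv_path: str | Path
) -> None:
    from .sequence_io import write_fasta

    basetypes = list(basetypes)
    write_fasta([(bt.basetype_id, bt.pattern) for bt in basetypes], fasta_path)
    pd.DataFrame(
        [
            {
                "basetype_id": bt.basetype_id,
                "morphospecies": bt.morphospecies,
                "n_obs": bt.n_obs,
                "specimens": ",".join(sorted(bt.specimens)),
            }
            for bt in basetypes
        ]
    ).to_csv(tsv_path, sep="\t", index=False)


def write_basegroups(basegroups: Iterable[Basegroup], tsv_path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "basegroup_id": bg.basegroup_id,
                "morphospecies": bg.morphospecies,
                "basetypes": ",".join(sorted(bg.basetypes)),
            }
            for bg in basegroups
        ]
    ).to_csv(tsv_path, sep="\t", index=False)
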