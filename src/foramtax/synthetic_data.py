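"""Synthetic barcode datasets with a known hierarchical truth.

The generator emulates a single-cell barcoding survey of planktonic
foraminifera: a rank-structured hierarchy (clade > morphospecies >
lineage > genotype > basegroup > basetype), multiple rDNA gene copies
per individual (so cloning one specimen reveals several co-occurring
basetypes), rare singleton error reads, and environmental OTUs drawn
both from sampled basetypes and from unsampled sister branches.

Sequences evolve down the hierarchy under a two-rate (K80-style)
substitution scheme: each branch mutates its parent's sequence at the
rank's expected divergence (jittered per branch), transitions favoured
kappa-fold over transversions. This matches the K80 distance used for
recovery, so estimated distances converge to the planted divergences.

Divergence defaults place the intragenomic and basegroup ranks close
together — a deliberate mirror of real rDNA data, where intra-individual
and population-level variation form one continuum — while the genotype
and higher ranks are separated by >= 3x so that species-level structure
is recoverable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .sequence_io import MarkerRegion, SequenceRecord, write_reference_set, write_fasta

__all__ = [
    "RANKS",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_reference_set",
    "simulate_env_otus",
    "make_chimera",
    "write_simulation",
]

#: Hierarchy ranks from the top down; "intragenomic" is the basetype level.
RANKS = ("clade", "morphospecies", "lineage", "genotype", "basegroup", "intragenomic")

# Per-branch multiplier on the rank divergence. The intragenomic rank gets
# the widest spread: intra-individual rDNA copy variation is highly
# heterogeneous and occasionally rivals population-level divergence, which
# interleaves the two lowest distance bands into the single continuum seen
# in real barcode data. Deep ranks vary less around their expectation.
_JITTER = {
    "intragenomic": (0.4, 2.0),
    "basegroup": (0.4, 1.5),
}
_JITTER_DEEP = (0.8, 1.2)

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

CountRange = int | tuple[int, int]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic survey; defaults are the study conditions."""

    seed: int = 0
    n_clades: int = 2
    n_morphospecies_per_clade: CountRange = (2, 3)
    n_lineages_per_morphospecies: CountRange = (1, 2)
    n_genotypes_per_lineage: CountRange = (1, 2)
    n_basegroups_per_genotype: CountRange = (1, 2)
    n_basetypes_per_basegroup: CountRange = (2, 3)
    divergence_per_rank: dict[str, float] = field(
        default_factory=lambda: {
            "intragenomic": 0.005,
            "basegroup": 0.0055,
            "genotype": 0.03,
            "lineage": 0.10,
            "morphospecies": 0.20,
            "clade": 0.30,
        }
    )
    transition_transversion_ratio: float = 2.0
    seq_length: int = 1000
    n_specimens_per_basegroup: int = 2
    n_clones_per_specimen: int = 6
    singleton_error_rate: float = 3e-4
    n_env_otus: int = 50
    fraction_novel_otus: float = 0.2
    read_count_distribution: dict[str, float] = field(
        default_factory=lambda: {"r": 0.5, "mean": 40.0}
    )
    size_fractions: tuple[str, ...] = ("pico", "nano", "micro", "meso", "bulk")
    n_samples: int = 4
    env_marker: str = "FORAM_37F"

    def validate(self) -> None:
        for name in (
            "n_clades",
            "n_specimens_per_basegroup",
            "n_clones_per_specimen",
            "n_env_otus",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "n_morphospecies_per_clade",
            "n_lineages_per_morphospecies",
            "n_genotypes_per_lineage",
            "n_basegroups_per_genotype",
            "n_basetypes_per_basegroup",
        ):
            lo, hi = _as_range(getattr(self, name))
            if lo < 1 or hi < lo:
                raise ValueError(f"{name}: invalid count range ({lo}, {hi})")
        if not 0 <= self.fraction_novel_otus <= 1:
            raise ValueError("fraction_novel_otus must be in [0, 1]")
        if not 0 <= self.singleton_error_rate < 1:
            raise ValueError("singleton_error_rate must be in [0, 1)")
        missing = set(RANKS) - set(self.divergence_per_rank)
        if missing:
            raise ValueError(f"divergence_per_rank missing ranks: {sorted(missing)}")
        # Divergence must strictly increase with rank height; equal
        # spacing makes rank recovery ill-posed, so refuse it.
        ordered = [self.divergence_per_rank[r] for r in reversed(RANKS)]
        for low_rank, high_rank, lo, hi in zip(
            reversed(RANKS), list(reversed(RANKS))[1:], ordered, ordered[1:]
        ):
            if not hi > lo:
                raise ValueError(
                    "degenerate rank spacing: divergence at rank "
                    f"{high_rank!r} ({hi}) must exceed rank {low_rank!r} ({lo}); "
                    "two ranks with equal divergence cannot be told apart"
                )

    def marker_regions(self) -> dict[str, MarkerRegion]:
        """Marker column intervals on the simulated master alignment.

        The foraminifera-specific fragment and the V9-style tail overlap
        partially, as on the real 18S.
        """
        L = self.seq_length
        v9_len = max(1, min(130, L // 4))
        foram_start = min(L // 6, max(0, L - 1))
        foram_end = max(foram_start + 1, int(L * 0.92))
        return {
            "FORAM_37F": MarkerRegion("FORAM_37F", foram_start, foram_end),
            "V9": MarkerRegion("V9", L - v9_len, L),
        }


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated survey."""

    taxonomy: dict[str, dict[str, str]]
    specimen_contents: dict[str, set[str]]
    basetype_seqs: dict[str, str]
    outgroup_seq: str
    otu_truth: dict[str, dict[str, str]] = field(default_factory=dict)

    def taxonomy_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.taxonomy, orient="index")
        df.index.name = "basetype_id"
        return df.sort_index()

    def n_units(self, level: str) -> int:
        return len({v[level] for v in self.taxonomy.values()})


def _as_range(value: CountRange) -> tuple[int, int]:
    if isinstance(value, int):
        return value, value
    lo, hi = value
    return int(lo), int(hi)


def _draw_count(rng: np.random.Generator, value: CountRange) -> int:
    lo, hi = _as_range(value)
    return int(rng.integers(lo, hi + 1))


def _evolve(
    seq: np.ndarray,
    divergence: float,
    kappa: float,
    rng: np.random.Generator,
    min_subs: int = 0,
    exact: bool = False,
) -> np.ndarray:
    """Mutate a coded sequence at the given per-site substitution probability.

    Given a substitution, a transition (A<->G, C<->T) happens with
    probability kappa/(kappa+2); each transversion with 1/(kappa+2).
    ``min_subs`` forces at least that many substituted sites (hierarchy
    branches must change the sequence, or two ranks would collapse).
    ``exact`` substitutes exactly round(divergence * length) sites — used
    for planted OTUs, whose realized divergence must not wander across a
    band boundary.
    """
    out = seq.copy()
    if exact:
        k = int(round(divergence * seq.size))
        hit = np.zeros(seq.size, dtype=bool)
        if k:
            hit[rng.choice(seq.size, size=min(k, seq.size), replace=False)] = True
    else:
        hit = rng.random(seq.size) < divergence
    if int(hit.sum()) < min_subs:
        extra = rng.choice(seq.size, size=min_subs, replace=False)
        hit[extra] = True
    n = int(hit.sum())
    if n == 0:
        return out
    old = out[hit]
    u = rng.random(n)
    p_ts = kappa / (kappa + 2.0)
    new = np.where(
        u < p_ts, old ^ 2, np.where(u < p_ts + (1 - p_ts) / 2, old ^ 1, old ^ 3)
    )
    out[hit] = new.astype(seq.dtype)
    return out


def _inject_errors(
    seq: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random miscalls at the per-site error rate."""
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    n = int(hit.sum())
    if n:
        shift = rng.integers(1, 4, size=n).astype(np.uint8)
        out[hit] = (out[hit] + shift) % 4
    return out


def _decode(seq: np.ndarray) -> str:
    return _DECODE[seq].tobytes().decode("ascii")


def _jitter(rng: np.random.Generator, rank: str = "clade") -> float:
    lo, hi = _JITTER.get(rank, _JITTER_DEEP)
    return float(rng.uniform(lo, hi))


def simulate_reference_set(
    config: SimulationConfig,
) -> tuple[list[SequenceRecord], pd.DataFrame, SyntheticTruth]:
    """Simulate the single-cell reference survey.

    Returns the read-level records (direct + clone reads, with singleton
    errors injected), their metadata table, and the ground truth.
    Deterministic for a fixed config seed.

    Every specimen carries basetypes of a single basegroup; each
    basegroup's first specimen carries all of its basetypes (cloning a
    well-sampled individual reveals the full variant set), which keeps
    the co-occurrence graph of each basegroup connected. Error injection
    spares the first three clone reads of every basetype so that with
    three or more clones per specimen no true basetype can fall below
    the >= 3-observation filter.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    kappa = config.transition_transversion_ratio
    div = config.divergence_per_rank
    L = config.seq_length

    root = rng.integers(0, 4, size=L, dtype=np.uint8)
    # The outgroup hangs off the root on a short pendant branch: any
    # positive length keeps it outside every ingroup clade (each clade is
    # at least one clade-level branch away), while staying short keeps
    # outgroup comparisons clear of K80 saturation.
    outgroup_seq = _decode(_evolve(root, 0.4 * div["clade"] * _jitter(rng), kappa, rng))

    taxonomy: dict[str, dict[str, str]] = {}
    basetype_seqs: dict[str, str] = {}
    bg_members: dict[str, list[str]] = {}
    seen_patterns: set[str] = set()
    n_bt = 0
    n_bg = 0
    def _count(first: bool, rng_range: CountRange) -> int:
        # The first unit at each level always branches (when the range
        # allows), so every rank of the hierarchy is represented and its
        # distance band can be calibrated from reference pairs.
        n = _draw_count(rng, rng_range)
        lo, hi = _as_range(rng_range)
        if first and hi >= 2:
            n = max(n, 2)
        return n

    for ci in range(1, config.n_clades + 1):
        clade = f"CL{ci}"
        clade_seq = _evolve(root, div["clade"] * _jitter(rng, "clade"), kappa, rng, min_subs=1)
        for mi in range(1, _count(ci == 1, config.n_morphospecies_per_clade) + 1):
            msp = f"{clade}.M{mi}"
            msp_seq = _evolve(clade_seq, div["morphospecies"] * _jitter(rng, "morphospecies"), kappa, rng, min_subs=1)
            for li in range(1, _count(ci == 1 and mi == 1, config.n_lineages_per_morphospecies) + 1):
                lineage = f"{msp}.I{li}"
                lin_seq = _evolve(msp_seq, div["lineage"] * _jitter(rng, "lineage"), kappa, rng, min_subs=1)
                for gi in range(1, _count(ci == 1 and mi == 1 and li == 1, config.n_genotypes_per_lineage) + 1):
                    genotype = f"{lineage}.G{gi}"
                    gt_seq = _evolve(lin_seq, div["genotype"] * _jitter(rng, "genotype"), kappa, rng, min_subs=1)
                    for _bi in range(_count(ci == 1 and mi == 1 and li == 1 and gi == 1, config.n_basegroups_per_genotype)):
                        n_bg += 1
                        bg = f"TG{n_bg:04d}"
                        bg_seq = _evolve(
                            gt_seq, div["basegroup"] * _jitter(rng, "basegroup"), kappa, rng,
                            min_subs=1,
                        )
                        bg_members[bg] = []
                        for _ti in range(
                            _count(n_bg == 1, config.n_basetypes_per_basegroup)
                        ):
                            n_bt += 1
                            bt = f"TB{n_bt:04d}"
                            bt_seq = _evolve(
                                bg_seq, div["intragenomic"] * _jitter(rng, "intragenomic"), kappa,
                                rng, min_subs=1,
                            )
                            # Basetypes are *distinct patterns* by definition;
                            # re-mutate on collision until unique.
                            while _decode(bt_seq) in seen_patterns:
                                bt_seq = _evolve(bt_seq, 0.0, kappa, rng, min_subs=1)
                            seen_patterns.add(_decode(bt_seq))
                            taxonomy[bt] = {
                                "clade": clade,
                                "morphospecies": msp,
                                "lvl1": lineage,
                                "lvl2": genotype,
                                "lvl3": bg,
                            }
                            basetype_seqs[bt] = _decode(bt_seq)
                            bg_members[bg].append(bt)

    records: list[SequenceRecord] = []
    specimen_contents: dict[str, set[str]] = {}
    obs_per_bt: dict[str, int] = {bt: 0 for bt in taxonomy}
    clean_clones: dict[str, int] = {bt: 0 for bt in taxonomy}
    first_specimen: dict[str, str] = {}
    n_sp = 0
    n_read = 0

    def emit(bt: str, specimen: str, station: str, stype: str) -> None:
        nonlocal n_read
        n_read += 1
        coded = np.frombuffer(
            basetype_seqs[bt].encode(), dtype=np.uint8
        )  # decoded string -> recode
        coded = np.searchsorted(np.frombuffer(b"ACGT", dtype=np.uint8), coded)
        # np.searchsorted on b"ACGT" works because ACGT are sorted bytes.
        coded = coded.astype(np.uint8)
        protected = stype == "direct" or clean_clones[bt] < 3
        if stype == "clone" and not protected and config.singleton_error_rate > 0:
            read = _inject_errors(coded, config.singleton_error_rate, rng)
        else:
            read = coded
        is_clean = bool(np.array_equal(read, coded))
        if stype == "clone" and is_clean:
            clean_clones[bt] += 1
        if is_clean:
            obs_per_bt[bt] += 1
        records.append(
            SequenceRecord(
                seq_id=f"SEQ{n_read:05d}",
                seq=_decode(read),
                specimen_id=specimen,
                morphospecies=taxonomy[bt]["morphospecies"],
                clade=taxonomy[bt]["clade"],
                station=station,
                sequencing_type=stype,
            )
        )

    for bg, members in bg_members.items():
        for si in range(config.n_specimens_per_basegroup):
            n_sp += 1
            specimen = f"SP{n_sp:04d}"
            station = f"ST{int(rng.integers(1, 9))}"
            if si == 0:
                carried = list(members)
            else:
                mask = rng.random(len(members)) < 0.8
                carried = [m for m, keep in zip(members, mask) if keep]
                if not carried:
                    carried = [members[int(rng.integers(len(members)))]]
            specimen_contents[specimen] = set(carried)
            for bt in carried:
                first_specimen.setdefault(bt, specimen)
            emit(carried[0], specimen, station, "direct")
            order = list(rng.permutation(len(carried)))
            for k in range(config.n_clones_per_specimen):
                emit(carried[order[k % len(carried)]], specimen, station, "clone")

    # Coverage top-up: guarantee min(3, clones/specimen) clean observations.
    target = min(3, config.n_clones_per_specimen)
    for bt, n_obs in obs_per_bt.items():
        while obs_per_bt[bt] < target:
            sp = first_specimen[bt]
            emit(bt, sp, "ST1", "clone")

    metadata = pd.DataFrame(
        [
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
    )
    truth = SyntheticTruth(
        taxonomy=taxonomy,
        specimen_contents=specimen_contents,
        basetype_seqs=basetype_seqs,
        outgroup_seq=outgroup_seq,
    )
    return records, metadata, truth


def _novelty_offsets(div: dict[str, float]) -> dict[str, float]:
    """Planting divergences: midpoint of each target rank's distance band.

    Pairwise distances between taxa whose most recent shared rank is r
    spread up to twice the summed jittered branch divergences below r,
    so a new branch planted at the midpoint between adjacent band
    *ceilings* (jitter included) lands unambiguously inside the target
    band.
    """

    def ceiling(*ranks: str) -> float:
        return 2.0 * sum(_JITTER.get(r, _JITTER_DEEP)[1] * div[r] for r in ranks)

    max_inter_bg = ceiling("intragenomic", "basegroup")
    max_inter_gt = ceiling("intragenomic", "basegroup", "genotype")
    max_inter_lin = ceiling("intragenomic", "basegroup", "genotype", "lineage")
    return {
        "new_genotype": (max_inter_bg + max_inter_gt) / 2.0,
        "new_lineage": (max_inter_gt + max_inter_lin) / 2.0,
    }


def simulate_env_otus(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[dict[str, str], pd.DataFrame]:
    """Simulate environmental OTUs against an existing reference truth.

    ``1 - fraction_novel_otus`` of the OTUs copy (or nearly copy, at
    half the intragenomic divergence) sampled basetypes; the rest are
    spawned from unsampled sister branches, alternating genotype-level
    and lineage-level divergence. Read counts per sample x size
    fraction follow a negative binomial with a lognormal per-OTU
    abundance factor (heavy-tailed, as metabarcode abundances are).

    Returns (OTU sequences over the configured marker, read-count
    table); truth classes are recorded in ``truth.otu_truth``.
    """
    config.validate()
    if not truth.basetype_seqs:
        raise ValueError("reference truth has no basetypes; run the reference "
                         "simulation first")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    kappa = config.transition_transversion_ratio
    marker = config.marker_regions()[config.env_marker]
    offsets = _novelty_offsets(config.divergence_per_rank)

    basetype_ids = sorted(truth.basetype_seqs)
    n_novel = int(round(config.n_env_otus * config.fraction_novel_otus))
    otus: dict[str, str] = {}
    truth.otu_truth = {}
    for k in range(1, config.n_env_otus + 1):
        otu_id = f"OTU{k:04d}"
        src = basetype_ids[int(rng.integers(len(basetype_ids)))]
        src_seq = np.frombuffer(truth.basetype_seqs[src].encode(), dtype=np.uint8)
        src_coded = np.searchsorted(
            np.frombuffer(b"ACGT", dtype=np.uint8), src_seq
        ).astype(np.uint8)
        if k <= n_novel:
            klass = "new_genotype" if k % 2 == 1 else "new_lineage"
            seq = _evolve(src_coded, offsets[klass], kappa, rng, exact=True)
        else:
            klass = "known_basegroup"
            if rng.random() < 0.5:
                seq = src_coded.copy()
            else:
                seq = _evolve(
                    src_coded,
                    config.divergence_per_rank["intragenomic"] / 2.0,
                    kappa,
                    rng,
                )
        otus[otu_id] = _decode(seq)[marker.start : marker.end]
        truth.otu_truth[otu_id] = {
            "true_class": klass,
            "true_nearest": src,
            "true_clade": truth.taxonomy[src]["clade"],
        }

    r = float(config.read_count_distribution.get("r", 0.5))
    mean = float(config.read_count_distribution.get("mean", 40.0))
    columns = [
        f"S{j}|{frac}"
        for j in range(1, config.n_samples + 1)
        for frac in config.size_fractions
    ]
    counts = np.zeros((config.n_env_otus, len(columns)), dtype=int)
    for i in range(config.n_env_otus):
        w = rng.lognormal(0.0, 1.5)
        mu = max(mean * w, 1e-9)
        p = r / (r + mu)
        counts[i] = rng.negative_binomial(r, p, size=len(columns))
    reads = pd.DataFrame(counts, index=list(otus), columns=columns)
    reads.index.name = "otu_id"
    return otus, reads


def make_chimera(seq_a: str, seq_b: str, breakpoint: float = 0.5) -> str:
    """Two-parent splice (test fixture for the chimera flag, nothing more)."""
    if len(seq_a) != len(seq_b):
        raise ValueError("chimera parents must be aligned to equal length")
    cut = int(len(seq_a) * breakpoint)
    return seq_a[:cut] + seq_b[cut:]


def write_simulation(
    outdir: str | Path,
    records: list[SequenceRecord],
    metadata: pd.DataFrame,
    truth: SyntheticTruth,
    otus: dict[str, str] | None = None,
    reads: pd.DataFrame | None = None,
) -> None:
    """Write FASTA/TSV/JSON artefacts of one simulated survey."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_reference_set(records, outdir / "reference.fasta", outdir / "metadata.tsv")
    if otus is not None:
        write_fasta(otus, outdir / "otus.fasta")
    if reads is not None:
        reads.to_csv(outdir / "otu_reads.tsv", sep="\t")
    payload: dict[str, Any] = {
        "taxonomy": truth.taxonomy,
        "specimen_contents": {k: sorted(v) for k, v in truth.specimen_contents.items()},
        "otu_truth": truth.otu_truth,
        "outgroup_seq": truth.outgroup_seq,
        "basetype_seqs": truth.basetype_seqs,
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
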