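# Methods

## Overview

`foramtax` implements a molecular-taxonomy pipeline for planktonic
foraminifera 18S rDNA barcodes and the re-annotation of environmental
metabarcode OTUs against it. The pipeline has two halves:

1. **Reference side** — single-cell barcode reads (direct Sanger reads
   and clone reads from the same specimens) are curated into an
   objective, three-level hierarchy of molecular operational taxonomic
   units (MOTUs) below the morphospecies level:
   * *basetypes*: distinct, exact sequence patterns observed at least
     three times (the threshold screens out rare sequencing errors,
     which appear as singleton or doubleton patterns);
   * *basegroups* (MOTU level 3): connected components of the bipartite
     basetype–specimen graph. Cloning reveals several distinct rDNA
     copies per individual, so basetypes co-occurring in one specimen
     belong to one organismal lineage;
   * MOTU levels 2 and 1: genotype- and lineage-level units from two
     independent species-delimitation methods (barcode-gap and
     branch-rate; below), cross-checked against the basegroups and the
     morphospecies labels.
2. **Environmental side** — each metabarcode OTU is assigned to one of
   the six major clades (Spinose, Non-Spinose, Microperforates, Basal,
   Monolamellar, Benthic) by its nearest reference under the Kimura
   two-parameter distance, and its nearest-reference distance is then
   placed within the empirical distance bands of the reference taxonomy
   to decide whether the OTU is already covered by a known basegroup or
   represents an unsampled genotype, lineage, or something beyond the
   known morphospecies-level variability.

All sequences are assumed substitution-aligned (uniform width); the
synthetic data are aligned by construction, and real data must be
aligned externally before entering the pipeline.

## Distances

Distances are Kimura (1980) two-parameter (K80):

d = −(1/2)·ln(1 − 2P − Q) − (1/4)·ln(1 − 2Q),

with P and Q the transition and transversion proportions among compared
sites. The contract for missing data is **pairwise deletion**: any
column where either sequence carries a gap or a non-ACGT symbol is
excluded from the comparison; IUPAC ambiguity codes are excluded
entirely rather than fractionally matched. Pairs compared over fewer
than `min_sites` columns (default 100) and pairs outside the K80 domain
(1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0, i.e. saturation) are *masked* — the
matrix keeps NaN and records the reason — rather than raised as errors,
because environmental OTUs legitimately vary in length and depth.
K80 ≥ p-distance wherever defined, with equality only for identical
pairs; this is exercised by the test suite over a grid of (P, Q).

## Trees

Trees are built by neighbor joining on the K80 matrix (scikit-bio's
implementation, wrapped so that additive matrices are reproduced
exactly and negative branch estimates are clamped to zero with an audit
annotation). Full ML optimisation is deliberately not performed: the
trees feed only the branch-rate delimitation and patristic-distance
summaries, both of which tolerate distance-based topologies. Rooting
places the root at the midpoint of the outgroup's pendant edge; the
outgroup is pruned (with unifurcations suppressed and edge lengths
summed) before delimitation, which preserves ingroup patristic
distances.

## Barcode-gap delimitation (ABGD-style)

For each prior intraspecific divergence P on a geometric ladder
(defaults 0.001–0.1 in 10 steps, the method's published defaults), the
ranked pairwise distances are scanned for the first *barcode gap* above
P. Our gap statistic is a documented dialect: a candidate gap — the
spacing between two consecutive ranked distances, ending above P —
qualifies when it exceeds `relative_gap` (default 1.5) times the
largest spacing anywhere below it. The rationale is that the distances
beneath a barcode gap are claimed to form one intraspecific continuum,
so any spacing of comparable size below the candidate disqualifies it;
this makes the statistic robust to the sparse, noisy tail of the
intraspecific distance cloud, where naive mean-spacing comparisons
flag extreme-value noise as structure. A prior with fewer than
`min_below` (default 8) distances below it cannot calibrate the
intraspecific scale and proposes nothing. Groups are formed by single
linkage below the gap midpoint.

Two partitions are reported, following the method's own designations:

* **initial** — the *coarsest* partition proposed anywhere on the prior
  ladder (larger priors absorb finer structure as intraspecific, so
  their gaps sit higher in the distance ranking);
* **recursive** — the initial partition re-split recursively: each
  group is rescanned on its own distance distribution over the full
  ladder until no further gap is found. Because recursion re-tests many
  small groups, its gap floor is inflated by a further factor of 1.5
  (an extreme-value correction: with n spacings below a candidate the
  observed maximum spacing sits about ln n above the mean, so the
  single-scan floor admits a non-trivial false-gap rate when applied
  many times). Recursive refines initial by construction.

When no prior yields a gap the method returns a single group — that is
a result, not an error.

## Branch-rate delimitation (PTP-style)

On the rooted, outgroup-pruned tree, a delimitation is a set of
"species root" nodes covering all leaves. Branch lengths strictly
inside species subtrees follow one exponential rate (within-species,
population process) and all other branches another (between-species,
speciation process); the log-likelihood is maximised analytically per
class (rate = n/Σlengths). The search is greedy hill-climbing over
split (replace a species root by its children) and merge (replace a
full sibling set by the parent) moves, from the single-species start,
the all-singleton start and 8 random antichain restarts (seeded). The
two-class model is accepted only if it beats the one-class null by more
than 1e-9 log-units; ties resolve to the coarsest solution, so
star-like trees return a single species. Branch lengths are floored at
1e-8 when scoring so zero-length cherries cannot produce infinite
rates. On trees with ≤ 6 leaves the search provably matches exhaustive
enumeration over all delimitations (tested on 50 random trees in two
branch-length regimes). This is the simple single-rate model: one
within-species rate shared across species, no per-species rates and no
Bayesian support values.

## Validation and consensus

A proposed partition is **invalidated** if it (a) splits any
basegroup's basetypes across two groups (*oversplit* — clones of one
individual cannot belong to two species), or (b) places basetypes of
two morphospecies in one group (*lump*). Both checks run independently
and all violations are recorded in a partition audit.

Among the valid partitions, **MOTU level 1** is the coarsest (fewest
groups; ties prefer the barcode-gap methods over the branch-rate
method, then lexicographic group content, for reproducibility).
**MOTU level 2** is the finest delimitation the valid methods jointly
propose, implemented as the common refinement of all valid partitions
(always including level 1, which guarantees the level-1 ⊇ level-2 ⊇
level-3 nesting). The refinement — rather than a single
most-groups partition — was chosen because a single method's marginal
merge of two genuine genotypes would otherwise leak inter-genotype
distances into the basegroup band and corrupt the novelty
classification downstream; two independent methods rarely blur the same
boundary. Since valid partitions never split basegroups, basegroups
nest within level 2 automatically. If *no* partition is valid, both
levels fall back to one MOTU per morphospecies, with a warning.

Delimitation runs separately within each clade (evolutionary rates
differ too much between clades for a shared gap or rate model), and the
per-clade taxonomies are concatenated with clade-prefixed unit labels.

## Rank bands and novelty classification

Every reference pair contributes its K80 distance to exactly one level,
the rank of the pair's most recent shared label: intra-basegroup,
inter-basegroup (same level-2 unit), inter-genotype (same level-1
unit), inter-lineage (same morphospecies), congeneric-morphospecies
(same clade), inter-clade. Levels with fewer than two contributing
pairs are marked unavailable. Band boundaries use the observed
*maximum* of each band — conservative against inventing novelty. An
OTU with nearest-reference distance d is classified by the first level
whose ceiling contains it: d ≤ max(inter-basegroup) means the OTU adds
no diversity (`known_basegroup`); then `new_genotype`, `new_lineage`,
and beyond the inter-lineage ceiling `exceeds_morphospecies`.
Unavailable bands fall through to the next level up (conservative,
warned). OTUs nearest a benthic reference are labelled
`benthic_affinity` at step 1 and skip step 2 (benthic clades are a
residual pool, not rank-banded). Classification always uses the K80
distance; patristic path-length matrices from the tree module can be
banded through the same shared-rank rule for concordance checks, but
the two metrics are never combined into one decision rule. A half-split chimera heuristic (the
two halves of the representative sequence assigning to different clades
with confident margins) is available but off by default — the
corresponding call on real data was a manual inspection.

The margin to the nearest other-clade reference is reported with every
step-1 call, keeping ambiguous clade assignments visible instead of
hiding them behind a hard decision rule.

## Synthetic surveys

The generator emulates the sampling design of a single-cell barcoding
survey with known truth. A six-rank hierarchy (clade > morphospecies >
lineage > genotype > basegroup > basetype) is evolved from a random
root sequence under a two-rate substitution scheme (transitions
favoured κ-fold, default κ = 2, matching the K80 distance used for
recovery so that estimated distances converge to the planted
divergences — verified at length 10,000 within 3 standard errors).

Key defaults and why:

* `seq_length` 1000 sites — the length of the real amplified fragment.
* `divergence_per_rank` (expected substitutions/site per branch):
  intragenomic 0.005, basegroup 0.0055, genotype 0.03, lineage 0.10,
  morphospecies 0.20, clade 0.30. The two lowest ranks are deliberately
  adjacent: intra-individual and population-level rDNA variation form
  one continuum in real barcode data (that continuum is the reason the
  basegroup construct exists), whereas the genotype and higher ranks
  are separated several-fold so species-level structure is recoverable.
  Rank divergences must increase strictly with rank height; a config
  with two equal ranks is refused as degenerate.
* per-branch jitter: each branch multiplies its rank divergence by a
  uniform factor — (0.4, 2.0) for intragenomic (copy variation is
  highly heterogeneous and occasionally rivals population divergence),
  (0.4, 1.5) for basegroup, (0.8, 1.2) for deeper ranks.
* counts: 2 clades, 2–3 morphospecies/clade, 1–2 lineages/morphospecies,
  1–2 genotypes/lineage, 1–2 basegroups/genotype, 2–3
  basetypes/basegroup. The first unit at each level always branches
  (where the range allows), so every rank is represented and every
  distance band can be calibrated in every survey. Basetype patterns
  are forced distinct (at least one substitution per branch, collision
  re-mutation) because a basetype *is* a distinct pattern by definition.
* specimens and reads: 2 specimens per basegroup; the first specimen
  carries the basegroup's full variant set (keeping each basegroup's
  co-occurrence graph connected), later specimens carry random subsets.
  Each specimen contributes one direct read and 6 clone reads allocated
  round-robin across its variants, with a top-up guaranteeing at least
  min(3, clones) observations per basetype.
* `singleton_error_rate` 3e-4 errors/site on clone reads. Errors are
  injected only into reads beyond the first three clean clones of each
  basetype, so the error process can never delete a true basetype from
  the ≥3-observation filter — planted truth stays recoverable by
  construction, which is the point of the generator.
* environmental OTUs: 50 per survey, 20% novel. Known OTUs copy a
  sampled basetype exactly or at half the intragenomic divergence.
  Novel OTUs are spawned from a sampled basetype at the midpoint
  between adjacent band *ceilings* (jitter included), alternating
  genotype-level and lineage-level targets, with an exact substitution
  count so the realized divergence cannot wander across a band
  boundary. Read counts are negative binomial (r = 0.5, mean 40) with a
  lognormal per-OTU abundance factor, over 4 samples × 5 size
  fractions.

What the generator does **not** emulate: alignment uncertainty and
indels (substitutions only, so all sequences stay aligned by
construction), PCR chimeras (a two-parent splice exists only as a test
fixture for the chimera flag), rate variation across sites,
amplification bias between size fractions, and the very uneven
per-species sampling depth of real collections. Passing recovery tests
therefore demonstrates the internal consistency of the pipeline under
its own model of the data, not robustness to alignment error or
primer/PCR artefacts.

## Measured recovery under the default conditions

These are the quantities `scripts/acceptance.py` recomputes (40 surveys
of ~290 reads each, 50 OTUs per survey; roughly 10 s on one CPU):
basetype and basegroup recovery are exact in all surveys, the MOTU
level-1 count matches the planted lineage count in all surveys, the
level-2 count matches the planted genotype count in ≥ 95% of surveys,
and the OTU novelty confusion matrix is diagonal in ≥ 95% of surveys.
The residual level-2 failures are marginal, genuinely ambiguous
draws — e.g. two genotypes whose planted separation lands at the low
end of its jitter range, or a genotype whose basegroups happen to
separate cleanly enough that a finer valid partition exists; both are
method properties, not bookkeeping errors.

## Numerical choices and degenerate inputs

* Distances: masked pairs propagate as NaN; NJ refuses masked matrices
  (subset or impute explicitly).
* Gap scan: ties in single linkage are resolved by scipy's
  deterministic ordering; group ids are canonicalised by smallest
  member, so partitions are invariant to input order.
* PTP: branch-length floor 1e-8; likelihood ties at 1e-9 resolution
  prefer fewer species.
* Fewer than 3 leaves (after outgroup pruning) yield a single-group
  partition; a clade with a single basetype gets trivial MOTU labels.
* All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); same seed, same bytes.

## Known limitations

* The barcode-gap dialect is faithful to the published method's intent
  (prior ladder, relative gap width 1.5, initial = coarsest /
  recursive = finest) but is not bit-compatible with the original
  server, whose exact version and behaviour are not recoverable.
* Real surveys need an external multiple aligner and a curated master
  alignment with marker column intervals; the package deliberately does
  not align.
* The branch-rate model shares one within-species rate across species;
  strongly heterogeneous clades would need a multi-rate model, which is
  out of scope.
* The ≥3-observation rule counts sequences by default (direct reads and
  clones each count once); counting distinct specimens instead is a
  documented switch (`count_unit="specimens"`), since three clones from
  one specimen arguably attest a pattern less independently.
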