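"""Distance-based tree inference and patristic distances.

Trees are :class:`dendropy.Tree` objects (newick in/out, branch lengths
in substitutions/site). Topologies come from neighbor joining on a K80
distance matrix; for the delimitation and banding steps downstream this
is a deliberate trade-off against full ML optimisation — both consumers
(the branch-length delimitation model and rank-band distance summaries)
are tolerant to distance-based topologies.

Negative NJ branch-length estimates are clamped to zero; the affected
edges keep an ``nj_clamped`` annotation for audit.
"""

from __future__ import annotations

import io
from pathlib import Path

import dendropy
import numpy as np
from skbio import DistanceMatrix as _SkDM
from skbio.tree import nj as _skbio_nj

from .distances import DistanceMatrix

__all__ = [
    "nj_tree",
    "root_with_outgroup",
    "prune_taxa",
    "patristic_distances",
    "read_newick",
    "write_newick",
    "leaf_labels",
]


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a newick tree (string or path); polytomies are resolved
    arbitrarily with zero-length edges."""
    text = source if str(source).lstrip().startswith("(") else Path(source).read_text()
    tree = dendropy.Tree.get(data=str(text), schema="newick")
    tree.resolve_polytomies()
    for edge in tree.preorder_edge_iter():
        if edge.length is None and edge.head_node is not tree.seed_node:
            edge.length = 0.0
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        Path(path).write_text(s)
    return s


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a complete distance matrix (unrooted).

    Additive matrices are reproduced exactly (up to floating point).
    Negative branch estimates are clamped to 0 and flagged.

    Raises
    ------
    ValueError
        If the matrix has masked entries (impute or subset first) or
        fewer than 3 taxa.
    """
    if dm.n_masked > 0:
        raise ValueError(
            f"{dm.n_masked} masked pairs in the distance matrix; NJ needs a "
            "complete matrix — subset the labels or impute first"
        )
    if len(dm) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    sk = _SkDM(dm.d, ids=dm.labels)
    newick = str(_skbio_nj(sk))
    tree = dendropy.Tree.get(data=newick, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            edge.annotations.add_new("nj_clamped", "true")
        elif edge.length is None and edge.head_node is not tree.seed_node:
            edge.length = 0.0
    return tree


def root_with_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root the tree at the midpoint of the outgroup's pendant edge.

    Returns a rooted clone; the input tree is left untouched.
    """
    rooted = tree.clone(depth=1)
    node = rooted.find_node_with_taxon_label(outgroup)
    if node is None:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    edge = node.edge
    half = (edge.length or 0.0) / 2.0
    rooted.reroot_at_edge(edge, length1=half, length2=half)
    rooted.is_rooted = True
    return rooted


def prune_taxa(tree: dendropy.Tree, labels: list[str]) -> dendropy.Tree:
    """Remove leaves by label (returns a pruned clone).

    Unifurcations introduced by pruning are suppressed with edge
    lengths summed, so ingroup patristic distances are preserved.
    """
    pruned = tree.clone(depth=1)
    pruned.prune_taxa_with_labels(labels)
    return pruned


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Path-length (sum of branch lengths) distances between all leaf pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(pdm.taxon_iter(), key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = pdm.patristic_distance(taxa[i], taxa[j])
            d[i, j] = d[j, i] = v
    return DistanceMatrix(labels, d, model="patristic")
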