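import itertools

import dendropy
import numpy as np
import pytest

from foramtax.distances import DistanceMatrix
from foramtax.delimitation import (
    Partition,
    abgd_partition,
    consensus_motus,
    delimitation_log_likelihood,
    geometric_priors,
    ptp_delimit,
    validate_partition,
)
from foramtax.nomenclature import Basegroup
from foramtax.phylogeny import read_newick


def _dm_from_values(labels, pairvals):
    n = len(labels)
    d = np.zeros((n, n))
    for (i, j), v in pairvals.items():
        d[i, j] = d[j, i] = v
    return DistanceMatrix(list(labels), d)


def _cluster_dm(rng, sizes, within, between):
    labels, cluster_of = [], {}
    for ci, size in enumerate(sizes):
        for k in range(size):
            lab = f"c{ci}x{k}"
            labels.append(lab)
            cluster_of[lab] = ci
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            base = within if cluster_of[labels[i]] == cluster_of[labels[j]] else between
            v = base * rng.uniform(0.9, 1.1)
            d[i, j] = d[j, i] = v
    return DistanceMatrix(labels, d), cluster_of


class TestAbgd:
    def test_two_clusters_found_at_low_priors(self):
        rng = np.random.default_rng(0)
        dm, cluster_of = _cluster_dm(rng, [5, 5], within=0.009, between=0.20)
        p = abgd_partition(dm, mode="initial")
        assert p.n_groups == 2
        groups = {}
        for lab, gid in p.groups.items():
            groups.setdefault(gid, set()).add(cluster_of[lab])
        assert all(len(v) == 1 for v in groups.values())

    def test_uniform_distances_single_group(self):
        labels = [f"t{i}" for i in range(6)]
        pairs = {(i, j): 0.005 for i in range(6) for j in range(i + 1, 6)}
        p = abgd_partition(_dm_from_values(labels, pairs))
        assert p.n_groups == 1 and p.prior is None

    def test_even_ladder_has_no_qualifying_gap(self):
        # sorted distances 0.01, 0.02, ..., 0.10: every spacing equals the
        # largest spacing below it, so no gap clears the 1.5x bar.
        labels = list("abcde")
        vals = dict(zip(itertools.combinations(range(5), 2),
                        [0.01 * k for k in range(1, 11)]))
        p = abgd_partition(_dm_from_values(labels, vals), min_below=2)
        assert p.n_groups == 1

    def test_recursive_refines_initial(self):
        # 4 tight clusters nested in 2 super-clusters
        rng = np.random.default_rng(1)
        labels, d = [], {}
        centers = {0: 0, 1: 0, 2: 1, 3: 1}  # cluster -> super-cluster
        for ci in range(4):
            for k in range(4):
                labels.append((ci, f"g{ci}x{k}"))
        n = len(labels)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ci, cj = labels[i][0], labels[j][0]
                if ci == cj:
                    v = 0.004 * rng.uniform(0.8, 1.2)
                elif centers[ci] == centers[cj]:
                    v = 0.05 * rng.uniform(0.9, 1.1)
                else:
                    v = 0.4 * rng.uniform(0.95, 1.05)
                mat[i, j] = mat[j, i] = v
        dm = DistanceMatrix([l[1] for l in labels], mat)
        init = abgd_partition(dm, mode="initial")
        rec = abgd_partition(dm, mode="recursive")
        assert init.n_groups == 2
        assert rec.n_groups == 4
        init_sets = init.group_sets()
        for sub in rec.group_sets():
            assert any(sub <= sup for sup in init_sets)

    def test_recursive_refines_initial_at_single_prior(self):
        rng = np.random.default_rng(2)
        dm, _ = _cluster_dm(rng, [5, 5], within=0.009, between=0.20)
        for prior in geometric_priors():
            init = abgd_partition(dm, priors=[prior], mode="initial")
            rec = abgd_partition(dm, priors=[prior], mode="recursive")
            init_sets = init.group_sets()
            for sub in rec.group_sets():
                assert any(sub <= sup for sup in init_sets)

    def test_masked_matrix_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError, match="masked"):
            abgd_partition(DistanceMatrix(["a", "b"], d))


def _enumerate_delimitations(tree):
    """All partitions of leaves into connected subtrees (oracle)."""

    def expand(node):
        yield [node]
        if not node.is_leaf():
            child_options = [list(expand(c)) for c in node.child_nodes()]
            for combo in itertools.product(*child_options):
                yield [r for sub in combo for r in sub]

    for roots in expand(tree.seed_node):
        if len(roots) == 1 and roots[0] is tree.seed_node:
            # single-species delimitation
            pass
        groups = {}
        for gid, r in enumerate(roots):
            for lf in r.leaf_iter():
                groups[lf.taxon.label] = gid
        yield groups


def _random_tree(rng, n_leaves, two_regime):
    taxa = [f"t{i}" for i in range(n_leaves)]
    ns = dendropy.TaxonNamespace()
    nodes = []
    for name in taxa:
        nd = dendropy.Node()
        nd.taxon = ns.new_taxon(name)
        nd.edge.length = float(rng.exponential(0.005) + 1e-4)
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        scale = 0.2 if (two_regime and rng.random() < 0.5) else 0.005
        parent.edge.length = float(rng.exponential(scale) + 1e-4)
        nodes = [n for n in nodes if n is not a and n is not b] + [parent]
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return tree


class TestPtp:
    def test_two_deep_clades_two_species(self):
        tree = read_newick(
            "((A:0.001,B:0.001):0.2,(C:0.001,(D:0.001,E:0.001):0.001):0.2);"
        )
        tree.is_rooted = True
        p = ptp_delimit(tree)
        assert p.n_groups == 2
        assert {frozenset(s) for s in p.group_sets()} == {
            frozenset("AB"),
            frozenset({"C", "D", "E"}),
        }

    def test_star_like_tree_single_species(self):
        tree = read_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        tree.is_rooted = True
        assert ptp_delimit(tree).n_groups == 1

    def test_two_leaves_plus_outgroup(self):
        tree = read_newick("((A:0.01,B:0.01):0.3,OUT:0.3);")
        tree.is_rooted = True
        p = ptp_delimit(tree, outgroup="OUT")
        # 2 ingroup leaves: one-species and all-singleton delimitations
        # tie in likelihood; the coarsest wins.
        assert p.n_groups == 1 and set(p.groups) == {"A", "B"}

    def test_missing_branch_lengths_rejected(self):
        tree = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        with pytest.raises(ValueError, match="lengths"):
            ptp_delimit(tree)

    @pytest.mark.parametrize("two_regime", [True, False])
    def test_matches_exhaustive_enumeration(self, two_regime):
        """Greedy + restarts equals exhaustive ML on all trees with <= 6
        leaves (25 random trees per branch-length regime)."""
        rng = np.random.default_rng(42 if two_regime else 43)
        for rep in range(25):
            n = int(rng.integers(3, 7))
            tree = _random_tree(rng, n, two_regime)
            found = ptp_delimit(tree, seed=rep)
            ll_found = delimitation_log_likelihood(tree, found.groups)
            best_ll, best_k = -np.inf, None
            for groups in _enumerate_delimitations(tree):
                ll = delimitation_log_likelihood(tree, groups)
                k = len(set(groups.values()))
                if ll > best_ll + 1e-9 or (abs(ll - best_ll) <= 1e-9 and k < best_k):
                    best_ll, best_k = ll, k
            null_ll = delimitation_log_likelihood(
                tree, {lf.taxon.label: 0 for lf in tree.leaf_node_iter()}
            )
            if best_ll <= null_ll + 1e-9:
                assert found.n_groups == 1
            else:
                assert ll_found == pytest.approx(best_ll, abs=1e-6)
                assert found.n_groups == best_k


BGS = [
    Basegroup("BG1", frozenset({"A", "B"}), "spA"),
    Basegroup("BG2", frozenset({"C"}), "spA"),
    Basegroup("BG3", frozenset({"D"}), "spB"),
]
MORPHO = {"A": "spA", "B": "spA", "C": "spA", "D": "spB"}


class TestValidation:
    def test_oversplit_basegroup_invalidates(self):
        p = Partition("PTP", {"A": "G1", "B": "G2", "C": "G2", "D": "G3"})
        v = validate_partition(p, BGS, MORPHO)
        assert v.valid is False
        assert ("oversplit", ("A", "B")) in v.violations

    def test_lumped_morphospecies_invalidates(self):
        p = Partition("ABGD_initial", {"A": "G1", "B": "G1", "C": "G1", "D": "G1"})
        v = validate_partition(p, BGS, MORPHO)
        assert v.valid is False
        assert any(kind == "lump" for kind, _ in v.violations)

    def test_both_violation_kinds_recorded_independently(self):
        p = Partition("PTP", {"A": "G1", "B": "G2", "C": "G2", "D": "G2"})
        v = validate_partition(p, BGS, MORPHO)
        kinds = {kind for kind, _ in v.violations}
        assert kinds == {"oversplit", "lump"}

    def test_basegroups_per_morphospecies_is_valid(self):
        p = Partition("PTP", {"A": "G1", "B": "G1", "C": "G1", "D": "G2"})
        v = validate_partition(p, BGS, MORPHO)
        assert v.valid is True and v.violations == []


class TestConsensus:
    def test_levels_from_coarsest_and_finest(self):
        coarse = Partition(
            "ABGD_initial",
            {"A": "G1", "B": "G1", "C": "G1", "D": "G2"},
            valid=True,
        )
        fine = Partition(
            "PTP", {"A": "G1", "B": "G1", "C": "G2", "D": "G3"}, valid=True
        )
        tax = consensus_motus([coarse, fine], BGS, MORPHO)
        assert tax["lvl1"].nunique() == 2
        assert tax["lvl2"].nunique() == 3
        assert tax.loc["A", "lvl2"] == tax.loc["B", "lvl2"]
        assert tax.loc["A", "lvl2"] != tax.loc["C", "lvl2"]

    def test_single_valid_partition_collapses_levels(self):
        only = Partition(
            "PTP", {"A": "G1", "B": "G1", "C": "G1", "D": "G2"}, valid=True
        )
        tax = consensus_motus([only], BGS, MORPHO)
        assert tax["lvl1"].nunique() == tax["lvl2"].nunique() == 2

    def test_no_valid_partition_falls_back_to_morphospecies(self):
        bad = Partition(
            "PTP", {"A": "G1", "B": "G2", "C": "G2", "D": "G3"}, valid=False
        )
        with pytest.warns(UserWarning, match="no valid delimitation"):
            tax = consensus_motus([bad], BGS, MORPHO)
        assert tax["lvl1"].nunique() == 2  # one per morphospecies
        # lvl1 and lvl2 are the same grouping (labels differ by prefix only)
        assert tax["lvl2"].nunique() == 2
        assert (tax.groupby("lvl1")["lvl2"].nunique() == 1).all()

    def test_nesting_always_holds(self):
        incompatible_a = Partition(
            "ABGD_initial", {"A": "G1", "B": "G1", "C": "G2", "D": "G3"}, valid=True
        )
        incompatible_b = Partition(
            "PTP", {"A": "G1", "B": "G1", "C": "G1", "D": "G2"}, valid=True
        )
        tax = consensus_motus([incompatible_a, incompatible_b], BGS, MORPHO)
        for child, parent in (("lvl2", "lvl1"), ("lvl3", "lvl2")):
            assert (tax.groupby(child)[parent].nunique() <= 1).all()
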