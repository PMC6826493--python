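"""Poisson distances, neighbor joining, bootstrap and subgroup assignment."""

import math

import dendropy
import numpy as np
import pytest

from mybsynnet.phylogeny import (
    DistanceMatrix,
    POISSON_SATURATION_DISTANCE,
    assign_subgroups,
    bootstrap_support,
    nj_tree,
    poisson_distance,
)


class TestPoissonDistance:
    def test_identical_sequences_distance_zero(self):
        dm = poisson_distance({"a": "ACDEF", "b": "ACDEF", "c": "ACDEF"})
        assert np.allclose(dm.d, 0.0)

    def test_half_different_gives_ln2(self):
        dm = poisson_distance({"a": "AAAA", "b": "AAVV"})
        assert dm.d[0, 1] == pytest.approx(-math.log(0.5))

    def test_saturated_pair_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="saturated"):
            dm = poisson_distance({"a": "AAAA", "b": "VVVV"})
        assert dm.d[0, 1] == POISSON_SATURATION_DISTANCE

    def test_pairwise_deletion_skips_gap_columns(self):
        dm = poisson_distance({"a": "A-CD", "b": "AVCD"})
        assert dm.d[0, 1] == 0.0  # the gapped column is not compared

    def test_no_comparable_columns_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            poisson_distance({"a": "A-", "b": "-A"})


class TestNjTree:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 0.3], [0.4, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], d)

    @pytest.mark.parametrize("seed", range(15))
    def test_additive_matrix_recovers_topology_and_lengths(self, seed):
        """On additive (tree-metric) input NJ must return the generating
        tree exactly: RF distance 0 and the induced path-length matrix
        equal to the input."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        true_tree, labels, D = random_additive_matrix(n, rng)
        est = nj_tree(DistanceMatrix(labels, D))
        tns = true_tree.taxon_namespace
        est.migrate_taxon_namespace(tns)
        rf = dendropy.calculate.treecompare.symmetric_difference(true_tree, est)
        assert rf == 0
        pdm = est.phylogenetic_distance_matrix()
        for i in range(n):
            for j in range(i + 1, n):
                got = pdm.patristic_distance(
                    tns.get_taxon(labels[i]), tns.get_taxon(labels[j])
                )
                assert got == pytest.approx(D[i, j], abs=1e-9)

    def test_five_taxon_topology_unique_by_enumeration(self):
        """Among all 15 unrooted 5-taxon topologies, only the generating
        one fits the additive matrix exactly (least-squares residual 0),
        and NJ picks it."""
        rng = np.random.default_rng(42)
        true_tree, labels, D = random_additive_matrix(5, rng)
        best_rss = {}
        for topo in enumerate_unrooted_trees(labels):
            rss = least_squares_fit_rss(topo, labels, D)
            key = topology_key(topo)
            best_rss[key] = min(rss, best_rss.get(key, np.inf))
        zero_fits = [k for k, v in best_rss.items() if v < 1e-12]
        assert len(zero_fits) == 1
        est = nj_tree(DistanceMatrix(labels, D))
        est.migrate_taxon_namespace(true_tree.taxon_namespace)
        assert topology_key(est) == zero_fits[0]

    def test_total_length_invariant_under_label_permutation(self):
        rng = np.random.default_rng(1)
        _, labels, D = random_additive_matrix(8, rng)
        t1 = nj_tree(DistanceMatrix(labels, D))
        perm = rng.permutation(len(labels))
        labels2 = [labels[i] for i in perm]
        D2 = D[np.ix_(perm, perm)]
        t2 = nj_tree(DistanceMatrix(labels2, D2))
        assert t1.length() == pytest.approx(t2.length(), abs=1e-9)


def random_additive_matrix(n, rng):
    """Random unrooted binary tree (built by stepwise random joins with
    positive branch lengths) and its patristic distance matrix."""
    labels = [f"t{i}" for i in range(n)]
    tns = dendropy.TaxonNamespace(labels)
    active = []
    for label in labels:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        active.append(node)
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[int(i)], active[int(j)]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = float(rng.uniform(0.05, 1.0))
        b.edge.length = float(rng.uniform(0.05, 1.0))
        active = [x for x in active if x is not a and x is not b] + [parent]
    root = dendropy.Node()
    for node in active:
        root.add_child(node)
        node.edge.length = float(rng.uniform(0.05, 1.0))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(
                tns.get_taxon(labels[i]), tns.get_taxon(labels[j])
            )
    return tree, labels, D


def enumerate_unrooted_trees(labels):
    """All unrooted binary topologies by stepwise leaf addition."""
    base = dendropy.Tree.get(
        data=f"({labels[0]},{labels[1]},{labels[2]});", schema="newick"
    )
    trees = [base]
    for label in labels[3:]:
        nxt = []
        for t in trees:
            edges = [
                e for e in t.preorder_edge_iter() if e.head_node is not t.seed_node
            ]
            for k in range(len(edges)):
                t2 = t.clone(depth=1)
                edges2 = [
                    e for e in t2.preorder_edge_iter()
                    if e.head_node is not t2.seed_node
                ]
                edge = edges2[k]
                old_head = edge.head_node
                parent = edge.tail_node
                parent.remove_child(old_head)
                mid = dendropy.Node()
                parent.add_child(mid)
                mid.add_child(old_head)
                leaf = dendropy.Node(
                    taxon=t2.taxon_namespace.require_taxon(label)
                )
                mid.add_child(leaf)
                nxt.append(t2)
        trees = nxt
    for t in trees:
        t.is_rooted = False
    return trees


def topology_key(tree):
    """Canonical set of non-trivial bipartitions (as leaf-name frozensets)."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    key = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(below) < len(leaves) - 1:
            key.add(frozenset({below, leaves - below}))
    return frozenset(key)


def least_squares_fit_rss(tree, labels, D):
    """Ordinary least-squares branch-length fit residual for a topology."""
    edges = [
        e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node
    ]
    leaf_of = {l.taxon.label: l for l in tree.leaf_node_iter()}
    rows, y = [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            path = path_edges(leaf_of[labels[i]], leaf_of[labels[j]])
            rows.append([1.0 if e in path else 0.0 for e in edges])
            y.append(D[i, j])
    A = np.array(rows)
    sol, *_ = np.linalg.lstsq(A, np.array(y), rcond=None)
    return float(((A @ sol - np.array(y)) ** 2).sum())


def path_edges(leaf_a, leaf_b):
    anc_a = []
    node = leaf_a
    while node is not None:
        anc_a.append(node)
        node = node.parent_node
    seen = set(id(x) for x in anc_a)
    path_b = []
    node = leaf_b
    while id(node) not in seen:
        path_b.append(node.edge)
        node = node.parent_node
    mrca = node
    path_a = []
    node = leaf_a
    while node is not mrca:
        path_a.append(node.edge)
        node = node.parent_node
    return set(path_a) | set(path_b)


class TestBootstrap:
    @pytest.fixture(scope="class")
    def clean_split_alignment(self):
        # two clearly distinct sequence groups: (a,b) vs (c,d)
        left = "A" * 30 + "C" * 30
        right = "V" * 30 + "C" * 30
        return {
            "a": left,
            "b": left[:-1] + "D",
            "c": right,
            "d": right[:-1] + "E",
        }

    def test_clean_split_gets_full_support(self, clean_split_alignment):
        tree = bootstrap_support(clean_split_alignment, n_reps=100, seed=0)
        supports = [
            float(n.label)
            for n in tree.preorder_node_iter()
            if n.label is not None and not n.is_leaf()
        ]
        assert supports and max(supports) >= 99.0

    def test_same_seed_reproduces_supports(self, clean_split_alignment):
        t1 = bootstrap_support(clean_split_alignment, n_reps=50, seed=7)
        t2 = bootstrap_support(clean_split_alignment, n_reps=50, seed=7)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_zero_replicates_rejected(self, clean_split_alignment):
        with pytest.raises(ValueError):
            bootstrap_support(clean_split_alignment, n_reps=0, seed=0)

    def test_random_alignment_supports_concentrate_low(self):
        rng = np.random.default_rng(0)
        # two-letter alphabet keeps random pairs below Poisson saturation
        aln = {
            f"s{i}": "".join(rng.choice(["A", "V"], size=120))
            for i in range(8)
        }
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            tree = bootstrap_support(aln, n_reps=100, seed=1)
        supports = [
            float(n.label)
            for n in tree.preorder_node_iter()
            if n.label is not None and not n.is_leaf()
        ]
        assert np.mean(supports) < 70.0


class TestAssignSubgroups:
    def _tree(self, newick):
        t = dendropy.Tree.get(data=newick, schema="newick")
        t.is_rooted = False
        return t

    def test_query_sister_to_pure_clade_gets_its_subgroup(self):
        t = self._tree("(((q1:1,r1:1)90:1,r2:1)95:1,(r3:1,r4:1)99:1,out:1);")
        refs = {"r1": "S6", "r2": "S6", "r3": "S4", "r4": "S4"}
        assert assign_subgroups(t, refs)["q1"] == "S6"

    def test_mixed_supported_clade_leaves_query_unassigned(self):
        # smallest *supported* clade around q1 mixes S4 and S7
        t = self._tree("(((q1:1,r1:1)40:1,r2:1)95:1,(r3:1,r4:1)99:1,out:1);")
        refs = {"r1": "S4", "r2": "S7", "r3": "S1", "r4": "S1"}
        assert assign_subgroups(t, refs)["q1"] is None

    def test_low_support_clades_are_skipped(self):
        # the pure S6 clade has support 30; the next one up mixes subgroups
        t = self._tree("(((q1:1,r1:1)30:1,r2:1)95:1,(r3:1,r4:1)99:1,out:1);")
        refs = {"r1": "S6", "r2": "S7", "r3": "S1", "r4": "S1"}
        assert assign_subgroups(t, refs)["q1"] is None

    def test_reference_gene_keeps_its_own_label(self):
        t = self._tree("((r1:1,r2:1)90:1,r3:1,q:1);")
        refs = {"r1": "S2", "r2": "S2", "r3": "S3"}
        assert assign_subgroups(t, refs)["r1"] == "S2"

    def test_no_references_rejected(self):
        t = self._tree("((a:1,b:1)90:1,c:1,d:1);")
        with pytest.raises(ValueError):
            assign_subgroups(t, {})
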