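"""Synteny network: CPM communities, categories, profiles, tandem arrays."""

import numpy as np
import pytest

from mybsynnet.collinearity import Anchor, SyntenyBlock
from mybsynnet.io_formats import Gene, GenomeRegistry
from mybsynnet.network import (
    SyntenyNetwork,
    build_network,
    categorize_cluster,
    cpm_communities,
    detect_tandem_arrays,
    phylo_profile,
    profile_dissimilarity,
    Cluster,
)

from oracles import cpm3_oracle


def net_from_edges(edges):
    net = SyntenyNetwork()
    for a, b in edges:
        net.add_edge(a, b)
    return net


def block_of(pairs, species_a="s1", species_b="s2"):
    anchors = tuple(
        Anchor(a, b, i, i, 1e-10) for i, (a, b) in enumerate(pairs)
    )
    return SyntenyBlock(species_a, "chr1", species_b, "chr1", "forward", anchors, float(len(anchors)))


class TestBuildNetwork:
    def test_family_family_anchor_becomes_edge(self):
        net = build_network([block_of([("f1", "f2"), ("f1", "x")])], {"f1", "f2"})
        assert net.nodes == {"f1", "f2"}
        assert net.edges == {("f1", "f2")}

    def test_mixed_anchor_excluded(self):
        net = build_network([block_of([("f1", "bg")])], {"f1"})
        assert net.edges == set()

    def test_multi_block_support_merges_to_one_edge(self):
        blocks = [block_of([("f1", "f2")]), block_of([("f1", "f2")])]
        net = build_network(blocks, {"f1", "f2"})
        assert net.edges == {("f1", "f2")}
        assert net.supporting_blocks("f1", "f2") == {0, 1}


class TestCpmCommunities:
    def test_triangle_is_one_cluster(self):
        clusters, residual = cpm_communities(net_from_edges([("a", "b"), ("b", "c"), ("a", "c")]))
        assert [set(c.members) for c in clusters] == [{"a", "b", "c"}]
        assert residual == []

    def test_triangles_sharing_edge_merge(self):
        edges = [("a", "b"), ("b", "c"), ("a", "c"), ("b", "d"), ("c", "d")]
        clusters, _ = cpm_communities(net_from_edges(edges))
        assert [set(c.members) for c in clusters] == [{"a", "b", "c", "d"}]

    def test_triangles_sharing_one_node_stay_separate(self):
        edges = [("a", "b"), ("b", "c"), ("a", "c"),
                 ("c", "d"), ("d", "e"), ("c", "e")]
        clusters, _ = cpm_communities(net_from_edges(edges))
        assert sorted((set(c.members) for c in clusters), key=min) == [
            {"a", "b", "c"}, {"c", "d", "e"},
        ]

    def test_isolated_edge_is_residual_pair(self):
        clusters, residual = cpm_communities(net_from_edges([("a", "b")]))
        assert clusters == []
        assert residual == [("a", "b")]

    def test_k_below_three_rejected(self):
        with pytest.raises(ValueError):
            cpm_communities(net_from_edges([("a", "b")]), k=2)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_triangle_percolation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        p = float(rng.uniform(0.05, 0.3))
        edges = {
            (f"n{i}", f"n{j}")
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < p
        }
        clusters, residual = cpm_communities(net_from_edges(edges))
        exp_comms, exp_residual = cpm3_oracle(edges)
        assert {frozenset(c.members) for c in clusters} == exp_comms
        assert set(residual) == exp_residual

    def test_communities_invariant_under_relabeling(self):
        rng = np.random.default_rng(3)
        edges = {
            (f"n{i}", f"n{j}")
            for i in range(20)
            for j in range(i + 1, 20)
            if rng.random() < 0.2
        }
        clusters, _ = cpm_communities(net_from_edges(edges))
        perm = {f"n{i}": f"m{(i * 7) % 20:02d}" for i in range(20)}
        mapped_edges = {(perm[a], perm[b]) for a, b in edges}
        clusters2, _ = cpm_communities(net_from_edges(mapped_edges))
        expect = {frozenset(perm[x] for x in c.members) for c in clusters}
        assert {frozenset(c.members) for c in clusters2} == expect

    def test_every_triangle_lies_in_exactly_one_community(self):
        rng = np.random.default_rng(5)
        edges = {
            (f"n{i}", f"n{j}")
            for i in range(25)
            for j in range(i + 1, 25)
            if rng.random() < 0.2
        }
        clusters, _ = cpm_communities(net_from_edges(edges))
        import itertools

        nodes = sorted({x for e in edges for x in e})
        for a, b, c in itertools.combinations(nodes, 3):
            if {(a, b), (a, c), (b, c)} <= edges:
                homes = [cl for cl in clusters if {a, b, c} <= cl.members]
                assert len(homes) == 1


def make_registry(spec):
    """spec: {species: (clade, [(chrom, [gene ids])])}"""
    reg = GenomeRegistry()
    for sp, (clade, chroms) in spec.items():
        genes = []
        for chrom, ids in chroms:
            for i, gid in enumerate(ids):
                genes.append(Gene(gid, sp, chrom, i * 1000 + 1, i * 1000 + 500, "+"))
        reg.add_species(sp, clade, genes)
    return reg


@pytest.fixture
def clade_registry():
    return make_registry(
        {
            "rice": ("monocot", [("c1", ["rice1", "rice2"])]),
            "maize": ("monocot", [("c1", ["maize1"])]),
            "rose": ("rosid", [("c1", ["rose1", "rose2"])]),
            "apple": ("rosid", [("c1", ["apple1"])]),
            "tomato": ("asterid", [("c1", ["tom1"])]),
            "potato": ("asterid", [("c1", ["pot1"])]),
            "lotus": ("basal_eudicot", [("c1", ["lot1"])]),
            "amborella": ("basal_angiosperm", [("c1", ["amb1"])]),
        }
    )


class TestCategorize:
    @pytest.mark.parametrize(
        "members, expected",
        [
            ({"rose1", "apple1"}, "rosid_specific"),
            ({"rice1", "maize1"}, "monocot_specific"),
            ({"tom1", "pot1"}, "asterid_specific"),
            ({"rice1", "rose1"}, "angiosperm_wide"),
            ({"amb1", "rose1"}, "angiosperm_wide"),
            ({"rose1", "tom1"}, "eudicot_specific"),
            ({"rose1", "lot1"}, "eudicot_specific"),
            ({"rose1", "rose2"}, "species_specific"),
        ],
    )
    def test_category_rules(self, clade_registry, members, expected):
        cl = Cluster(0, frozenset(members), frozenset())
        assert categorize_cluster(cl, clade_registry) == expected


class TestPhyloProfile:
    def test_counts_and_row_sums(self, clade_registry):
        clusters = [
            Cluster(0, frozenset({"rose1", "rose2", "apple1"}), frozenset()),
            Cluster(1, frozenset({"rice1", "tom1"}), frozenset()),
        ]
        order = ["rice", "maize", "rose", "apple", "tomato", "potato", "lotus", "amborella"]
        prof = phylo_profile(clusters, clade_registry, order)
        assert prof.loc[0, "rose"] == 2
        assert prof.loc[0, "apple"] == 1
        assert prof.loc[0].sum() == 3
        assert prof.loc[1].sum() == 2
        assert list(prof.columns) == order

    def test_planted_copy_numbers_recovered(self, null_dataset, tmp_path):
        """The profile of truth clusters equals the planted per-species counts."""
        from mybsynnet.pipeline import load_dataset

        datadir, truth = null_dataset
        ds = load_dataset(datadir)
        lineages = sorted(truth.family_lineages)
        clusters = [
            Cluster(i, frozenset(
                g for g, lin in truth.cluster_labels.items() if lin == linid
            ), frozenset())
            for i, linid in enumerate(lineages)
        ]
        prof = phylo_profile(clusters, ds.registry, ds.species_order)
        # null fixture: one copy per lineage per species
        assert (prof.to_numpy() == 1).all()


class TestProfileDissimilarity:
    def test_jaccard_values(self, clade_registry):
        clusters = [
            Cluster(0, frozenset({"rose1", "apple1"}), frozenset()),  # {rose, apple}
            Cluster(1, frozenset({"apple1", "tom1"}), frozenset()),  # {apple, tomato}
            Cluster(2, frozenset({"rice1"}), frozenset()),  # {rice}
            Cluster(3, frozenset({"rose2", "apple1"}), frozenset()),  # {rose, apple}
        ]
        order = ["rice", "maize", "rose", "apple", "tomato", "potato", "lotus", "amborella"]
        prof = phylo_profile(clusters, clade_registry, order)
        dmat, newick = profile_dissimilarity(prof)
        assert dmat.loc[0, 3] == pytest.approx(0.0)  # identical presence
        assert dmat.loc[0, 2] == pytest.approx(1.0)  # disjoint species
        assert dmat.loc[0, 1] == pytest.approx(1 - 1 / 3)  # share apple of three
        assert newick.endswith(";") and "0" in newick


class TestTandemArrays:
    def test_adjacent_family_genes_form_array(self):
        reg = make_registry(
            {"sp": ("rosid", [("c1", [f"g{i}" for i in range(20)])])}
        )
        arrays = detect_tandem_arrays(reg, {"g10", "g11", "g12"})
        assert len(arrays) == 1
        assert arrays[0].gene_ids == ("g10", "g11", "g12")

    def test_spacer_above_threshold_breaks_array(self):
        reg = make_registry(
            {"sp": ("rosid", [("c1", [f"g{i}" for i in range(20)])])}
        )
        assert detect_tandem_arrays(reg, {"g10", "g17"}, max_spacer=5) == []
        arrays = detect_tandem_arrays(reg, {"g10", "g16"}, max_spacer=5)
        assert len(arrays) == 1  # exactly 5 intervening genes is allowed

    def test_planted_seven_gene_array_recovered_exactly(self, tandem7_dataset):
        from mybsynnet.pipeline import load_dataset

        datadir, truth = tandem7_dataset
        ds = load_dataset(datadir)
        members = {g for genes in truth.family_members.values() for g in genes}
        arrays = detect_tandem_arrays(ds.registry, members)
        sevens = [a for a in arrays if a.size == 7]
        assert len(sevens) == 1
        truth_seven = next(a for a in truth.tandem_arrays if len(a["genes"]) == 7)
        assert list(sevens[0].gene_ids) == truth_seven["genes"]
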