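"""Collinear block chaining: contract examples and oracle equivalence."""

import numpy as np
import pytest

from mybsynnet.collinearity import (
    Anchor,
    ChainParams,
    all_pairs_synteny,
    build_anchors,
    chain_anchors,
)
from mybsynnet.io_formats import Gene, GenomeRegistry, HomologyHit

from oracles import chain_oracle


def anchors_from_ranks(pairs):
    return [Anchor(f"a{ra}", f"b{rb}", ra, rb, 1e-10) for ra, rb in pairs]


def block_shapes(blocks):
    return [
        (b.orientation, tuple((a.rank_a, a.rank_b) for a in b.anchors))
        for b in blocks
    ]


class TestChainAnchors:
    def test_five_anchor_diagonal_is_one_forward_block(self):
        blocks = chain_anchors(anchors_from_ranks([(i, i) for i in range(5)]))
        assert len(blocks) == 1
        assert blocks[0].orientation == "forward"
        assert len(blocks[0]) == 5

    def test_four_anchor_diagonal_is_below_minimum(self):
        assert chain_anchors(anchors_from_ranks([(i, i) for i in range(4)])) == []

    def test_gap_of_26_genes_splits_the_chain(self):
        # 3 + 3 anchors with a 26-gene gap in both genomes: neither run
        # reaches the 5-anchor minimum on its own
        pairs = [(i, i) for i in range(3)] + [(i + 29, i + 29) for i in range(3)]
        assert chain_anchors(anchors_from_ranks(pairs)) == []
        # the same geometry with a 25-gene gap chains into one block
        pairs_ok = [(i, i) for i in range(3)] + [(i + 28, i + 28) for i in range(3)]
        blocks = chain_anchors(anchors_from_ranks(pairs_ok))
        assert len(blocks) == 1 and len(blocks[0]) == 6

    def test_antidiagonal_is_one_inverted_block(self):
        blocks = chain_anchors(anchors_from_ranks([(i, 10 - i) for i in range(5)]))
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"

    def test_blocks_satisfy_structural_invariants(self):
        rng = np.random.default_rng(7)
        pairs = {(int(a), int(b)) for a, b in rng.integers(0, 30, size=(60, 2))}
        blocks = chain_anchors(anchors_from_ranks(sorted(pairs)), min_block=3, max_gap=5)
        seen = set()
        for blk in blocks:
            assert len(blk) >= 3
            ra = [a.rank_a for a in blk.anchors]
            rb = [a.rank_b for a in blk.anchors]
            assert ra == sorted(ra) and len(set(ra)) == len(ra)
            if blk.orientation == "forward":
                assert rb == sorted(rb) and len(set(rb)) == len(rb)
            else:
                assert rb == sorted(rb, reverse=True)
            for (a1, b1), (a2, b2) in zip(zip(ra, rb), zip(ra[1:], rb[1:])):
                assert a2 - a1 - 1 <= 5 and abs(b2 - b1) - 1 <= 5
            for a in blk.anchors:
                key = (a.rank_a, a.rank_b)
                assert key not in seen  # each anchor in at most one block
                seen.add(key)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_oracle_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        pairs = {(int(a), int(b)) for a, b in rng.integers(0, 12, size=(n, 2))}
        anchors = anchors_from_ranks(sorted(pairs))
        max_gap = int(rng.integers(2, 7))
        got = block_shapes(chain_anchors(anchors, min_block=3, max_gap=max_gap))
        expected = chain_oracle(anchors, min_block=3, max_gap=max_gap)
        assert got == expected


def _registry_two_species(n=10, species=("spA", "spB")):
    reg = GenomeRegistry()
    for sp in species:
        genes = [
            Gene(f"{sp}_g{i}", sp, "chr1", i * 1000 + 1, i * 1000 + 500, "+")
            for i in range(n)
        ]
        reg.add_species(sp, "rosid", genes)
    return reg


class TestBuildAnchors:
    def test_top_n_truncation_per_target_genome(self):
        reg = _registry_two_species()
        hits = [
            HomologyHit("spA_g0", f"spB_g{i}", 1e-20, 300 - i) for i in range(7)
        ]
        grouped = build_anchors(reg, hits, top_n=5)
        total = sum(len(v) for v in grouped.values())
        assert total == 5
        # best-bitscore subjects kept
        kept = {a.gene_b for v in grouped.values() for a in v}
        assert kept == {f"spB_g{i}" for i in range(5)}

    def test_reciprocal_hits_deduplicate(self):
        reg = _registry_two_species()
        hits = [
            HomologyHit("spA_g0", "spB_g0", 1e-20, 300),
            HomologyHit("spB_g0", "spA_g0", 1e-25, 300),
        ]
        grouped = build_anchors(reg, hits)
        anchors = [a for v in grouped.values() for a in v]
        assert len(anchors) == 1
        assert anchors[0].evalue == 1e-25  # best e-value kept

    def test_unknown_gene_rejected(self):
        reg = _registry_two_species()
        with pytest.raises(KeyError, match="ghost"):
            build_anchors(reg, [HomologyHit("ghost", "spB_g0", 1e-20, 100)])


class TestAllPairsSynteny:
    def test_identical_genomes_give_one_full_block(self):
        reg = _registry_two_species(n=10)
        hits = [
            HomologyHit(f"spA_g{i}", f"spB_g{i}", 1e-30, 500.0) for i in range(10)
        ]
        blocks = all_pairs_synteny(reg, hits, ChainParams())
        assert len(blocks) == 1
        assert len(blocks[0]) == 10

    def test_self_comparison_without_duplication_gives_no_blocks(self):
        reg = _registry_two_species(n=10, species=("only",))
        blocks = all_pairs_synteny(reg, [], ChainParams())
        assert blocks == []

    def test_wgd_self_comparison_recovers_duplicated_segments(self, wgd_dataset):
        from mybsynnet.pipeline import load_dataset

        datadir, truth = wgd_dataset
        ds = load_dataset(datadir)
        blocks = all_pairs_synteny(ds.registry, ds.hits, ChainParams())
        wgd_species = "rB"  # fixture plants the event on this terminal branch
        self_blocks = [
            b for b in blocks
            if b.species_a == wgd_species and b.species_b == wgd_species
        ]
        assert self_blocks, "duplicated segments must be visible in self-synteny"
        dup_anchor_genes = {
            g for b in self_blocks for pair in b.gene_pairs() for g in pair
        }
        assert len(dup_anchor_genes) > 0.8 * truth.gene_counts[wgd_species]

    def test_null_fixture_ortholog_chromosomes_one_spanning_block(self, null_dataset):
        """With zero rearrangement each orthologous chromosome pair yields
        exactly one block covering all shared genes."""
        from mybsynnet.pipeline import load_dataset

        datadir, truth = null_dataset
        ds = load_dataset(datadir)
        blocks = all_pairs_synteny(ds.registry, ds.hits, ChainParams())
        cross = {}
        for b in blocks:
            if b.species_a != b.species_b:
                cross.setdefault(
                    (b.species_a, b.chrom_a, b.species_b, b.chrom_b), []
                ).append(b)
        # 4 species -> 6 genome pairs x 2 orthologous chromosome pairs
        assert len(cross) == 12
        for key, blist in cross.items():
            assert len(blist) == 1, key
            assert len(blist[0]) >= 50
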