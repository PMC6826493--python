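"""Collinear (synteny) block detection from pairwise homology and gene order.

A collinear block is a chained run of homologous gene pairs (anchors)
whose order is conserved between two chromosomes, allowing bounded gaps.
Following the usual collinearity-scan conventions, a block needs at
least ``min_block`` anchors (default 5 genes) and consecutive anchors
may be separated by at most ``max_gap`` intervening genes (default 25)
in *both* genomes.  All computation is in gene-rank units.

Chains are extracted iteratively, best first, by dynamic programming run
in both orientations (forward and inverted).  The chain score is
``n_anchors - 0.02 * total_gaps``; because the total gap of a monotone
chain is determined by its endpoints and length, distinct chains can tie
exactly, so the selection rule is made total: higher score, then forward
before inverted, then the lexicographically smallest (rankA, rankB)
sequence.  Scores are handled as integers (x50) so ties are exact.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

from .io_formats import GenomeRegistry, HomologyHit

__all__ = [
    "Anchor",
    "SyntenyBlock",
    "ChainParams",
    "build_anchors",
    "chain_anchors",
    "all_pairs_synteny",
]

GAP_PENALTY_X50 = 1  # 0.02 per gap unit, in fiftieths of an anchor


@dataclasses.dataclass(frozen=True)
class Anchor:
    """A homologous gene pair anchoring one matched position of a block."""

    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    evalue: float


@dataclasses.dataclass(frozen=True)
class SyntenyBlock:
    species_a: str
    chrom_a: str
    species_b: str
    chrom_b: str
    orientation: str  # "forward" | "inverted"
    anchors: tuple[Anchor, ...]
    score: float

    def __len__(self) -> int:
        return len(self.anchors)

    def gene_pairs(self) -> list[tuple[str, str]]:
        return [(a.gene_a, a.gene_b) for a in self.anchors]


@dataclasses.dataclass(frozen=True)
class ChainParams:
    min_block: int = 5
    max_gap: int = 25
    top_n: int = 5


ChromPair = tuple[str, str, str, str]  # species_a, chrom_a, species_b, chrom_b


def build_anchors(
    registry: GenomeRegistry,
    hits: Iterable[HomologyHit],
    top_n: int = 5,
) -> dict[ChromPair, list[Anchor]]:
    """Turn homology hits into candidate anchors, grouped by chromosome pair.

    For each query gene only its ``top_n`` best-bitscore subjects per
    target genome are kept (the usual collinearity-scan truncation that
    stops large families from flooding the dot plot).  Anchors are
    deduplicated as unordered gene pairs, keeping the best e-value, and
    each pair is stored with (species, chrom, rank) in canonical order.
    """
    per_query: dict[str, dict[str, list[HomologyHit]]] = {}
    for hit in hits:
        if hit.query_id not in registry:
            raise KeyError(f"hit references unknown query gene {hit.query_id!r}")
        if hit.subject_id not in registry:
            raise KeyError(f"hit references unknown subject gene {hit.subject_id!r}")
        target = registry.gene(hit.subject_id).species
        per_query.setdefault(hit.query_id, {}).setdefault(target, []).append(hit)

    best: dict[tuple[str, str], float] = {}
    for query in per_query:
        for target, target_hits in per_query[query].items():
            target_hits.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
            for hit in target_hits[:top_n]:
                key = tuple(sorted((hit.query_id, hit.subject_id)))
                if key not in best or hit.evalue < best[key]:
                    best[key] = hit.evalue

    grouped: dict[ChromPair, list[Anchor]] = {}
    for (g1, g2), evalue in best.items():
        a, b = registry.gene(g1), registry.gene(g2)
        if (a.species, a.chrom, a.rank) > (b.species, b.chrom, b.rank):
            a, b = b, a
        key = (a.species, a.chrom, b.species, b.chrom)
        grouped.setdefault(key, []).append(
            Anchor(a.gene_id, b.gene_id, a.rank, b.rank, evalue)
        )
    for anchors in grouped.values():
        anchors.sort(key=lambda x: (x.rank_a, x.rank_b))
    return grouped


def _best_chain(
    anchors: list[Anchor], max_gap: int, inverted: bool
) -> tuple[int, list[Anchor]] | None:
    """Best-scoring valid chain in one orientation.

    Returns (score_x50, chain) where the chain is the lexicographically
    smallest among equal-score optima, or None if there are no anchors.
    """
    if not anchors:
        return None
    sign = -1 if inverted else 1
    # sort by (rank_a, oriented rank_b); suffix DP over this order
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].rank_a, sign * anchors[i].rank_b))
    ra = [anchors[i].rank_a for i in order]
    rb = [sign * anchors[i].rank_b for i in order]
    n = len(order)
    g = [50] * n  # best score (x50) of a chain starting at i
    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n):
            gap_a = ra[j] - ra[i] - 1
            if gap_a > max_gap:
                break  # ra is non-decreasing in j
            if gap_a < 0:
                continue  # same rank_a: cannot chain
            gap_b = rb[j] - rb[i] - 1
            if gap_b < 0 or gap_b > max_gap:
                continue
            cand = 50 + g[j] - GAP_PENALTY_X50 * (gap_a + gap_b)
            if cand > g[i]:
                g[i] = cand
    best_score = max(g)

    def lexkey(i: int) -> tuple[int, int]:
        return (anchors[order[i]].rank_a, anchors[order[i]].rank_b)

    # lex-smallest optimal chain: greedily take the smallest feasible anchor
    start = min((i for i in range(n) if g[i] == best_score), key=lexkey)
    chain_idx = [start]
    cur = start
    while True:
        # a net-zero extension (step gap penalty == anchor value) can tie a
        # prefix with its extension; the prefix is lex-smaller, so stop as
        # soon as ending here is already optimal
        if g[cur] == 50:
            break
        nxt = None
        for j in range(cur + 1, n):
            gap_a = ra[j] - ra[cur] - 1
            if gap_a > max_gap:
                break
            if gap_a < 0:
                continue
            gap_b = rb[j] - rb[cur] - 1
            if gap_b < 0 or gap_b > max_gap:
                continue
            if 50 + g[j] - GAP_PENALTY_X50 * (gap_a + gap_b) == g[cur]:
                if nxt is None or lexkey(j) < lexkey(nxt):
                    nxt = j
        if nxt is None:
            break
        chain_idx.append(nxt)
        cur = nxt
    return best_score, [anchors[order[i]] for i in chain_idx]


def chain_anchors(
    anchors: Iterable[Anchor],
    min_block: int = 5,
    max_gap: int = 25,
    chrom_pair: ChromPair = ("A", "chrA", "B", "chrB"),
) -> list[SyntenyBlock]:
    """Extract collinear blocks from the anchors of one chromosome pair.

    Chains are peeled off best-score-first (each anchor belongs to at
    most one block) until no remaining chain reaches ``min_block``.
    """
    remaining = list(anchors)
    blocks: list[SyntenyBlock] = []
    while remaining:
        candidates = []
        for orient_rank, inverted in ((0, False), (1, True)):
            result = _best_chain(remaining, max_gap, inverted)
            if result is None:
                continue
            score, chain = result
            seq = tuple((a.rank_a, a.rank_b) for a in chain)
            candidates.append(((-score, orient_rank, seq), inverted, score, chain))
        if not candidates:
            break
        _, inverted, score, chain = min(candidates, key=lambda c: c[0])
        if len(chain) < min_block:
            break
        taken = set(id(a) for a in chain)
        remaining = [a for a in remaining if id(a) not in taken]
        sp_a, ch_a, sp_b, ch_b = chrom_pair
        blocks.append(
            SyntenyBlock(
                species_a=sp_a, chrom_a=ch_a, species_b=sp_b, chrom_b=ch_b,
                orientation="inverted" if inverted else "forward",
                anchors=tuple(chain),
                score=score / 50.0,
            )
        )
    return blocks


def all_pairs_synteny(
    registry: GenomeRegistry,
    hits: Iterable[HomologyHit],
    params: ChainParams | None = None,
) -> list[SyntenyBlock]:
    """Collinear blocks for every genome pair, self-comparisons included.

    In a self chromosome comparison the identity diagonal (a gene paired
    with itself) and tandem-adjacent pairs (|rank_a - rank_b| <= 1) are
    excluded, so only genuinely duplicated segments are reported.
    """
    if params is None:
        params = ChainParams()
    grouped = build_anchors(registry, hits, top_n=params.top_n)
    blocks: list[SyntenyBlock] = []
    for key in sorted(grouped):
        sp_a, ch_a, sp_b, ch_b = key
        anchors = grouped[key]
        if sp_a == sp_b and ch_a == ch_b:
            anchors = [
                a for a in anchors
                if a.gene_a != a.gene_b and abs(a.rank_a - a.rank_b) > 1
            ]
        blocks.extend(
            chain_anchors(anchors, params.min_block, params.max_gap, chrom_pair=key)
        )
    return blocks


def blocks_to_table(blocks: list[SyntenyBlock]) -> "pandas.DataFrame":  # noqa: F821
    """Flatten blocks to one row per anchor for TSV export."""
    import pandas as pd

    rows = []
    for block_id, blk in enumerate(blocks):
        for a in blk.anchors:
            rows.append(
                {
                    "block_id": block_id,
                    "species_a": blk.species_a,
                    "chrom_a": blk.chrom_a,
                    "species_b": blk.species_b,
                    "chrom_b": blk.chrom_b,
                    "orientation": blk.orientation,
                    "n_anchors": len(blk),
                    "score": blk.score,
                    "gene_a": a.gene_a,
                    "gene_b": a.gene_b,
                    "rank_a": a.rank_a,
                    "rank_b": a.rank_b,
                }
            )
    return pd.DataFrame(rows)
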