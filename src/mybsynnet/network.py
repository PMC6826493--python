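"""Family synteny network: construction, clique-percolation clustering,
lineage categorization, phylogenetic profiling and tandem-array detection.

Nodes are family genes; an edge joins two family genes that appear as an
anchor pair inside a detected collinear block (a "syntelog" pair).
Communities are found by clique percolation (CPM): a k-clique community
is the union of k-cliques reachable from one another through overlaps of
k-1 nodes.  With the conventional k = 3, isolated syntenic pairs (edges
in no triangle) fall outside every community and are reported separately
as residual pairs.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import k_clique_communities

from .collinearity import SyntenyBlock
from .io_formats import Gene, GenomeRegistry

__all__ = [
    "SyntenyNetwork",
    "Cluster",
    "CATEGORIES",
    "build_network",
    "cpm_communities",
    "categorize_cluster",
    "phylo_profile",
    "profile_dissimilarity",
    "detect_tandem_arrays",
    "TandemArray",
]

CATEGORIES = (
    "angiosperm_wide",
    "eudicot_specific",
    "monocot_specific",
    "rosid_specific",
    "asterid_specific",
    "species_specific",
)


class SyntenyNetwork:
    """Family-restricted synteny graph.

    Each edge carries the ids of the collinear blocks supporting it.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def add_edge(self, a: str, b: str, block_id: int | None = None) -> None:
        if a == b:
            return
        if self.graph.has_edge(a, b):
            if block_id is not None:
                self.graph.edges[a, b]["blocks"].add(block_id)
        else:
            blocks = {block_id} if block_id is not None else set()
            self.graph.add_edge(a, b, blocks=blocks)

    def supporting_blocks(self, a: str, b: str) -> set[int]:
        return set(self.graph.edges[a, b]["blocks"])


@dataclasses.dataclass
class Cluster:
    cluster_id: int
    members: frozenset[str]
    species_set: frozenset[str]
    category: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def build_network(
    blocks: Sequence[SyntenyBlock], family_members: Iterable[str]
) -> SyntenyNetwork:
    """Restrict collinear-block anchors to family-family gene pairs.

    One edge is created per anchor pair whose *both* genes are family
    members; the same pair seen in several blocks yields a single edge
    with merged block support.
    """
    family = set(family_members)
    net = SyntenyNetwork()
    for block_id, blk in enumerate(blocks):
        for ga, gb in blk.gene_pairs():
            if ga in family and gb in family:
                net.add_edge(ga, gb, block_id)
    return net


def cpm_communities(
    network: SyntenyNetwork, k: int = 3
) -> tuple[list[Cluster], list[tuple[str, str]]]:
    """k-clique-percolation communities plus residual syntenic pairs.

    Residual pairs are connected components of exactly two nodes — edges
    that take part in no triangle and therefore in no k>=3 community.
    Cluster ids are assigned in decreasing size order, ties broken by the
    smallest member gene id, so numbering is deterministic.
    """
    if k < 3:
        raise ValueError("clique percolation requires k >= 3")
    graph = network.graph
    communities = [frozenset(c) for c in k_clique_communities(graph, k)]
    communities.sort(key=lambda c: (-len(c), min(c)))
    clusters = [
        Cluster(cluster_id=i, members=c, species_set=frozenset())
        for i, c in enumerate(communities)
    ]
    residual = sorted(
        tuple(sorted(comp))
        for comp in nx.connected_components(graph)
        if len(comp) == 2
    )
    return clusters, [(a, b) for a, b in residual]


def categorize_cluster(cluster: Cluster, registry: GenomeRegistry) -> str:
    """Assign one of the six lineage-specificity categories.

    - species_specific: members from a single species;
    - monocot_/rosid_/asterid_specific: >1 species, all of one clade;
    - eudicot_specific: >1 species, clades within {rosid, asterid,
      basal_eudicot} but not a single-clade case;
    - angiosperm_wide: spans a monocot (or basal angiosperm) and a
      eudicot lineage.
    """
    species = {registry.gene(g).species for g in cluster.members}
    clades = {registry.clade(sp) for sp in species}
    if len(species) == 1:
        return "species_specific"
    if clades == {"monocot"}:
        return "monocot_specific"
    if clades == {"rosid"}:
        return "rosid_specific"
    if clades == {"asterid"}:
        return "asterid_specific"
    eudicot_clades = {"rosid", "asterid", "basal_eudicot"}
    if clades <= eudicot_clades:
        return "eudicot_specific"
    return "angiosperm_wide"


def annotate_clusters(
    clusters: Iterable[Cluster], registry: GenomeRegistry
) -> list[Cluster]:
    """Fill species_set and category for each cluster (in place, returned)."""
    out = []
    for cl in clusters:
        cl.species_set = frozenset(registry.gene(g).species for g in cl.members)
        cl.category = categorize_cluster(cl, registry)
        out.append(cl)
    return out


def phylo_profile(
    clusters: Sequence[Cluster],
    registry: GenomeRegistry,
    species_order: Sequence[str],
) -> pd.DataFrame:
    """Cluster-by-species gene-count matrix (the phylogenetic profile).

    Rows are clusters (by id), columns species in the given (tree)
    order; each cell counts that cluster's genes in that species, so row
    sums equal cluster sizes.
    """
    missing = {registry.gene(g).species for cl in clusters for g in cl.members} - set(
        species_order
    )
    if missing:
        raise ValueError(f"species_order is missing species: {sorted(missing)}")
    mat = np.zeros((len(clusters), len(species_order)), dtype=int)
    col = {sp: j for j, sp in enumerate(species_order)}
    index = []
    for i, cl in enumerate(clusters):
        index.append(cl.cluster_id)
        for g in cl.members:
            mat[i, col[registry.gene(g).species]] += 1
    return pd.DataFrame(mat, index=pd.Index(index, name="cluster_id"), columns=list(species_order))


def profile_dissimilarity(
    profile: pd.DataFrame,
) -> tuple[pd.DataFrame, str]:
    """Jaccard dissimilarity between clusters' species sets, plus a Ward
    dendrogram in Newick form.

    Rows are binarized to presence/absence before the Jaccard
    computation (1 - |A∩B| / |A∪B|).  A cluster present in no species
    is, by convention, at dissimilarity 1 from everything (warned).
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    if len(profile) < 2:
        raise ValueError("need at least 2 clusters")
    presence = (profile.to_numpy() > 0)
    n = presence.shape[0]
    if (~presence.any(axis=1)).any():
        warnings.warn("all-zero profile row: dissimilarity 1 to everything by convention")
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = (presence[i] | presence[j]).sum()
            inter = (presence[i] & presence[j]).sum()
            d = 1.0 if union == 0 else 1.0 - inter / union
            dmat[i, j] = dmat[j, i] = d
    labels = [str(i) for i in profile.index]
    linkage = hierarchy.linkage(squareform(dmat, checks=False), method="ward")
    newick = _linkage_to_newick(linkage, labels)
    return pd.DataFrame(dmat, index=profile.index, columns=profile.index), newick


def _linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Convert a scipy linkage matrix to a Newick string (deterministic)."""
    n = len(labels)

    def render(node: int) -> tuple[str, float]:
        if node < n:
            return labels[node], 0.0
        row = linkage[node - n]
        left, right = int(row[0]), int(row[1])
        height = float(row[2])
        ls, lh = render(left)
        rs, rh = render(right)
        return (
            f"({ls}:{height / 2 - lh:.6f},{rs}:{height / 2 - rh:.6f})",
            height / 2,
        )
    tree, _ = render(2 * n - 2)
    return tree + ";"


@dataclasses.dataclass(frozen=True)
class TandemArray:
    species: str
    chrom: str
    gene_ids: tuple[str, ...]  # in rank order

    @property
    def size(self) -> int:
        return len(self.gene_ids)


def detect_tandem_arrays(
    registry: GenomeRegistry,
    family_members: Iterable[str],
    max_spacer: int = 5,
) -> list[TandemArray]:
    """Maximal runs of >=2 family genes on one chromosome separated by at
    most ``max_spacer`` intervening non-family genes."""
    family = set(family_members)
    arrays: list[TandemArray] = []
    for sp in registry.species:
        chroms = sorted({g.chrom for g in registry.genes_of(sp)})
        for chrom in chroms:
            fam_genes = [
                g for g in registry.chromosome(sp, chrom) if g.gene_id in family
            ]
            run: list[Gene] = []
            for g in fam_genes:
                if run and g.rank - run[-1].rank - 1 > max_spacer:
                    if len(run) >= 2:
                        arrays.append(TandemArray(sp, chrom, tuple(x.gene_id for x in run)))
                    run = []
                run.append(g)
            if len(run) >= 2:
                arrays.append(TandemArray(sp, chrom, tuple(x.gene_id for x in run)))
    return arrays
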