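"""Distance-based phylogenetics: Poisson-corrected protein distances,
neighbor-joining trees, column-bootstrap support, and subgroup assignment
of unlabeled genes against a reference-annotated species.

Trees are dendropy objects throughout, so Newick IO and bipartition
arithmetic come for free.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "DistanceMatrix",
    "poisson_distance",
    "nj_tree",
    "bootstrap_support",
    "assign_subgroups",
    "POISSON_SATURATION_DISTANCE",
]

# p >= 1 - 1/e leaves -ln(1-p) >= 1 undefined or explosive; saturated
# pairs are clipped to a large finite distance so NJ stays finite.
POISSON_SATURATION_DISTANCE = 3.0


@dataclasses.dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")


def poisson_distance(
    alignment: Mapping[str, str], complete_deletion: bool = False
) -> DistanceMatrix:
    """Poisson-corrected pairwise distances d = -ln(1 - p) from an
    aligned protein FASTA dict.

    p is the proportion of differing residues over comparable columns;
    by default columns where either sequence is gapped are skipped per
    pair (pairwise deletion); ``complete_deletion`` drops every column
    containing any gap before comparison.  Saturated pairs
    (p >= 1 - 1/e) are clipped to POISSON_SATURATION_DISTANCE.
    """
    labels = list(alignment)
    seqs = [alignment[l] for l in labels]
    length = len(seqs[0])
    for l, s in zip(labels, seqs):
        if len(s) != length:
            raise ValueError(f"sequence {l!r} has length {len(s)} != {length}")
    arrs = [np.frombuffer(s.upper().encode(), dtype="S1") for s in seqs]
    gap = [np.isin(a, [b"-", b"."]) for a in arrs]
    if complete_deletion:
        keep = ~np.logical_or.reduce(gap)
        arrs = [a[keep] for a in arrs]
        gap = [np.zeros(keep.sum(), dtype=bool) for _ in arrs]
    n = len(labels)
    d = np.zeros((n, n))
    p_max = 1.0 - 1.0 / math.e
    n_saturated = 0
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            p = float((arrs[i][ok] != arrs[j][ok]).sum()) / m
            if p >= p_max:
                n_saturated += 1
                dist = POISSON_SATURATION_DISTANCE
            else:
                dist = -math.log(1.0 - p)
            d[i, j] = d[j, i] = dist
    if n_saturated:
        warnings.warn(
            f"{n_saturated} saturated pair(s) (p >= 1 - 1/e) clipped to "
            f"d = {POISSON_SATURATION_DISTANCE}"
        )
    return DistanceMatrix(labels, d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining (Saitou–Nei) tree from a distance matrix.

    The result is unrooted (trifurcating at the last join).  A negative
    branch length produced by the agglomeration is clamped to zero and
    its deficit moved to the sister branch, preserving path lengths.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    D = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic tie-break: smallest (i, j) in active order
        i_loc, j_loc = np.unravel_index(int(np.argmin(q)), q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = D[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(li, 0.0)
        nodes[j].edge.length = max(lj, 0.0)
        # new distances
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, new_row])
        new_col = np.append(new_row, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = dendropy.Node()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(length, 0.0)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def _resample_columns(
    alignment: Mapping[str, str], rng: np.random.Generator
) -> dict[str, str]:
    length = len(next(iter(alignment.values())))
    cols = rng.integers(0, length, size=length)
    return {label: "".join(seq[c] for c in cols) for label, seq in alignment.items()}


def bootstrap_support(
    alignment: Mapping[str, str],
    n_reps: int = 1000,
    seed: int = 0,
    complete_deletion: bool = False,
) -> dendropy.Tree:
    """NJ tree with internal-edge bootstrap supports (percent).

    Alignment columns are resampled with replacement ``n_reps`` times;
    each replicate runs the same Poisson-distance + NJ pipeline; the
    support of an internal edge is the percentage of replicates whose
    tree contains the same bipartition.  Supports are written as
    internal node labels.  Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    base = nj_tree(poisson_distance(alignment, complete_deletion))
    base.encode_bipartitions()
    counts: dict[int, int] = {}
    for _ in range(n_reps):
        rep_aln = _resample_columns(alignment, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep_tree = nj_tree(
                poisson_distance(rep_aln, complete_deletion)
            )
        rep_tree.migrate_taxon_namespace(base.taxon_namespace)
        rep_tree.encode_bipartitions()
        for bip in rep_tree.bipartition_encoding:
            counts[bip.split_bitmask] = counts.get(bip.split_bitmask, 0) + 1
    for edge in base.preorder_edge_iter():
        node = edge.head_node
        if node.is_leaf() or node is base.seed_node:
            continue
        pct = 100.0 * counts.get(edge.bipartition.split_bitmask, 0) / n_reps
        node.label = f"{pct:.0f}"
    return base


def assign_subgroups(
    tree: dendropy.Tree,
    reference_labels: Mapping[str, str],
    min_support: float = 50.0,
) -> dict[str, str | None]:
    """Assign each unlabeled leaf the subgroup of its nearest supported
    reference clade.

    Walking from the query leaf toward the root of the (trifurcation-
    rooted) tree, the first internal node whose bootstrap support is at
    least ``min_support`` and whose clade contains reference genes is
    inspected: if those references all carry one subgroup label S, the
    query is assigned S; if they mix subgroups, the query stays
    unassigned (None).  Reference genes keep their own labels.
    """
    if not reference_labels:
        raise ValueError("no reference labels given")
    result: dict[str, str | None] = {}
    leaf_sets: dict[dendropy.Node, set[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leaf_sets[node] = {node.taxon.label}
        else:
            leaf_sets[node] = set().union(*(leaf_sets[c] for c in node.child_nodes()))
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        if name in reference_labels:
            result[name] = reference_labels[name]
            continue
        assigned: str | None = None
        node = leaf.parent_node
        while node is not None:
            support = _node_support(node, tree)
            if support is not None and support >= min_support:
                refs = {
                    reference_labels[x]
                    for x in leaf_sets[node]
                    if x in reference_labels
                }
                if refs:
                    assigned = refs.pop() if len(refs) == 1 else None
                    break
            node = node.parent_node
        result[name] = assigned
    return result


def _node_support(node: dendropy.Node, tree: dendropy.Tree) -> float | None:
    if node is tree.seed_node or node.is_leaf():
        return None
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None
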