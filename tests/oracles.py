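"""Independent brute-force oracles used by the test suite.

Each oracle re-derives the expected answer by exhaustive enumeration,
deliberately sharing no code with the implementation under test.
"""

from __future__ import annotations

import itertools

GAP_PENALTY_X50 = 1


# ---------------------------------------------------------------------------
# clique percolation by explicit triangle overlap (k = 3)


def cpm3_oracle(edges: set[tuple[str, str]]):
    """Communities = unions of triangles connected through shared edges;
    residual pairs = 2-node connected components."""
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    nodes = sorted(adj)
    triangles = []
    for a, b, c in itertools.combinations(nodes, 3):
        if b in adj[a] and c in adj[a] and c in adj[b]:
            triangles.append(frozenset((a, b, c)))
    # union triangles sharing >= 2 nodes (an edge)
    parent = list(range(len(triangles)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(triangles)):
        for j in range(i + 1, len(triangles)):
            if len(triangles[i] & triangles[j]) >= 2:
                parent[find(i)] = find(j)
    groups: dict[int, set[str]] = {}
    for i, tri in enumerate(triangles):
        groups.setdefault(find(i), set()).update(tri)
    communities = {frozenset(g) for g in groups.values()}

    # residual pairs: connected components of size exactly 2
    seen: set[str] = set()
    residual = set()
    for start in nodes:
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in comp:
                    comp.add(y)
                    stack.append(y)
        seen |= comp
        if len(comp) == 2:
            residual.add(tuple(sorted(comp)))
    return communities, residual


# ---------------------------------------------------------------------------
# collinear chain extraction by exhaustive chain enumeration


def _enumerate_chains(anchors, max_gap, inverted):
    """Yield every valid chain (list of anchors) in one orientation."""
    sign = -1 if inverted else 1
    idx = sorted(range(len(anchors)),
                 key=lambda i: (anchors[i].rank_a, sign * anchors[i].rank_b))

    def ok(i, j):
        gap_a = anchors[j].rank_a - anchors[i].rank_a - 1
        gap_b = sign * anchors[j].rank_b - sign * anchors[i].rank_b - 1
        return 0 <= gap_a <= max_gap and 0 <= gap_b <= max_gap

    def extend(chain):
        yield list(chain)
        last = chain[-1]
        for j in idx:
            if ok(last, j):
                chain.append(j)
                yield from extend(chain)
                chain.pop()

    for i in idx:
        yield from extend([i])


def _chain_key(anchors, chain, inverted):
    score = 50 * len(chain)
    for a, b in zip(chain, chain[1:]):
        gap_a = anchors[b].rank_a - anchors[a].rank_a - 1
        gap_b = abs(anchors[b].rank_b - anchors[a].rank_b) - 1
        score -= GAP_PENALTY_X50 * (gap_a + gap_b)
    seq = tuple((anchors[i].rank_a, anchors[i].rank_b) for i in chain)
    return (-score, 1 if inverted else 0, seq)


def chain_oracle(anchors, min_block, max_gap):
    """Iterative best-first chain extraction by full enumeration.

    Returns a list of (orientation, tuple of (rank_a, rank_b)) blocks
    with the same total selection rule as the implementation: maximal
    score (anchors - 0.02 * gaps), forward before inverted, then the
    lexicographically smallest rank sequence.
    """
    remaining = list(anchors)
    blocks = []
    while remaining:
        best = None
        for inverted in (False, True):
            for chain in _enumerate_chains(remaining, max_gap, inverted):
                key = _chain_key(remaining, chain, inverted)
                if best is None or key < best[0]:
                    best = (key, inverted, [remaining[i] for i in chain])
        if best is None:
            break
        _, inverted, chain = best
        if len(chain) < min_block:
            break
        blocks.append(
            ("inverted" if inverted else "forward",
             tuple((a.rank_a, a.rank_b) for a in chain))
        )
        taken = {id(a) for a in chain}
        remaining = [a for a in remaining if id(a) not in taken]
    return blocks


# ---------------------------------------------------------------------------
# Nei-Gojobori difference counts by explicit path enumeration

_BASES = "TCAG"
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE = dict(zip(_CODONS, _AA))


def ng_diff_oracle(codon1: str, codon2: str):
    """(syn, nonsyn) observed-difference split for one codon pair,
    averaged with equal weight over all stop-free substitution orders
    (all orders, stop steps nonsynonymous, if every order is blocked)."""
    positions = [i for i in range(3) if codon1[i] != codon2[i]]

    def path_counts(order, allow_stop):
        cur, syn, non = codon1, 0, 0
        for pos in order:
            nxt = cur[:pos] + codon2[pos] + cur[pos + 1 :]
            if GENETIC_CODE[nxt] == "*" and not allow_stop:
                return None
            syn += GENETIC_CODE[nxt] == GENETIC_CODE[cur]
            non += GENETIC_CODE[nxt] != GENETIC_CODE[cur]
            cur = nxt
        return syn, non

    orders = list(itertools.permutations(positions))
    counts = [path_counts(o, False) for o in orders]
    counts = [c for c in counts if c is not None]
    if not counts:
        counts = [path_counts(o, True) for o in orders]
    if not counts:
        return 0.0, 0.0
    return (sum(c[0] for c in counts) / len(counts),
            sum(c[1] for c in counts) / len(counts))
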