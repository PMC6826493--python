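"""Recovery metrics comparing pipeline output against simulator truth."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

__all__ = ["cluster_recovery_ari"]


def cluster_recovery_ari(
    recovered: Sequence[Iterable[str]],
    truth_labels: Mapping[str, int],
) -> float:
    """Adjusted Rand index between recovered synteny clusters and the
    planted cluster labels.

    Every gene in ``truth_labels`` is scored; family genes missing from
    all recovered clusters count as singletons.  A gene in several
    overlapping communities is scored with its first (largest) cluster.
    """
    from sklearn.metrics import adjusted_rand_score

    assignment: dict[str, int] = {}
    for cid, members in enumerate(recovered):
        for g in members:
            assignment.setdefault(g, cid)
    next_singleton = len(recovered)
    genes = sorted(truth_labels)
    pred = []
    for g in genes:
        if g not in assignment:
            assignment[g] = next_singleton
            next_singleton += 1
        pred.append(assignment[g])
    true = [truth_labels[g] for g in genes]
    return float(adjusted_rand_score(true, pred))
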