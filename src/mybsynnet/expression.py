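"""Expression summaries downstream of read counting: FPKM normalization,
expressed-gene detection, qPCR relative expression (2^-ddCq), and
stage-trend concordance between gene pairs."""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "fpkm",
    "expressed_genes",
    "delta_delta_cq",
    "trend_concordance",
]


@dataclasses.dataclass
class CountMatrix:
    """Gene-by-sample fragment counts with per-gene effective lengths
    (bp) and per-sample total mapped fragments."""

    counts: pd.DataFrame  # genes x samples, integer
    lengths: pd.Series  # bp per gene
    totals: pd.Series  # mapped fragments per sample

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths[self.lengths.isna()].index.tolist()
            raise ValueError(f"missing gene lengths: {missing}")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        self.totals = self.totals.reindex(self.counts.columns)
        if self.totals.isna().any():
            raise ValueError("missing per-sample totals")


def fpkm(cm: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments:
    FPKM[g, s] = count[g, s] * 1e9 / (length[g] * total[s])."""
    if (cm.totals == 0).any():
        zero = cm.totals[cm.totals == 0].index.tolist()
        raise ValueError(f"zero mapped-fragment total for samples: {zero}")
    return (
        cm.counts * 1e9
    ).div(cm.lengths, axis=0).div(cm.totals, axis=1)


def expressed_genes(
    expr: pd.DataFrame,
    family_members: Iterable[str],
    min_fpkm: float = 1.0,
    min_samples: int = 1,
) -> set[str]:
    """Family genes expressed at >= min_fpkm in >= min_samples samples
    (boundaries inclusive)."""
    family = [g for g in family_members if g in expr.index]
    hits = (expr.loc[family] >= min_fpkm).sum(axis=1)
    return set(hits[hits >= min_samples].index)


def delta_delta_cq(
    cq_target: Mapping[str, float | Sequence[float]],
    cq_reference: Mapping[str, float | Sequence[float]],
    calibrator_sample: str,
) -> dict[str, float]:
    """Relative expression per sample by the 2^-ddCq method.

    Replicate Cq values are averaged first; dCq = Cq_target - Cq_ref per
    sample; ddCq subtracts the calibrator's dCq; fold = 2^-ddCq (so the
    calibrator maps to exactly 1).
    """
    def mean(v) -> float:
        arr = np.atleast_1d(np.asarray(v, dtype=float))
        return float(arr.mean())

    if calibrator_sample not in cq_target:
        raise KeyError(f"calibrator sample {calibrator_sample!r} not in target Cq")
    folds: dict[str, float] = {}
    d_cq = {}
    for sample, cq in cq_target.items():
        if sample not in cq_reference:
            raise KeyError(f"missing reference Cq for sample {sample!r}")
        d_cq[sample] = mean(cq) - mean(cq_reference[sample])
    calib = d_cq[calibrator_sample]
    for sample, dc in d_cq.items():
        folds[sample] = float(2.0 ** (-(dc - calib)))
    return folds


def trend_concordance(
    expr: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    ordered_samples: Sequence[str],
) -> str:
    """Compare stage-to-stage expression trends of two genes over ordered
    developmental stages: 'concordant' if every change agrees in sign,
    'discordant' if every change is opposite, else 'mixed'.  Zero changes
    are ties compatible with either sign.
    """
    if len(ordered_samples) < 3:
        raise ValueError("need at least 3 ordered samples")
    a = expr.loc[gene_a, list(ordered_samples)].to_numpy(dtype=float)
    b = expr.loc[gene_b, list(ordered_samples)].to_numpy(dtype=float)
    sa = np.sign(np.diff(a))
    sb = np.sign(np.diff(b))
    informative = (sa != 0) & (sb != 0)
    if not informative.any():
        return "mixed"  # ties only: no evidence either way
    agree = sa[informative] == sb[informative]
    if agree.all():
        return "concordant"
    if (~agree).all():
        return "discordant"
    return "mixed"
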