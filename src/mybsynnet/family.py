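"""R2R3-MYB family identification from domain-scan hits, and domain
conservation profiles.

The R2R3 subfamily is defined by exactly two tandem MYB DNA-binding
domain repeats (R2 and R3).  Proteins with a single repeat (1R / MYB-
related) or three repeats (3R) are excluded.  Membership is decided from
the per-domain rows of a profile-HMM scan: a gene is a family member iff
it carries exactly two non-overlapping significant domain hits.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np

from .io_formats import DomainHit

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
MAX_BITS = math.log2(len(AMINO_ACIDS))

__all__ = [
    "FamilyCall",
    "MotifProfile",
    "identify_family",
    "motif_profile",
    "compare_profiles",
    "AMINO_ACIDS",
    "MAX_BITS",
]


@dataclasses.dataclass(frozen=True)
class FamilyCall:
    gene_id: str
    n_domains: int
    domain_evalues: tuple[float, ...]
    is_member: bool


def _merge_overlapping(hits: list[DomainHit]) -> list[DomainHit]:
    """Merge hits that share protein positions, keeping the lower e-value.

    Overlapping reports of the same region must not be double-counted as
    two repeats.
    """
    kept: list[DomainHit] = []
    for hit in sorted(hits, key=lambda h: (h.evalue, h.ali_start)):
        if any(h.ali_start <= hit.ali_end and hit.ali_start <= h.ali_end for h in kept):
            continue
        kept.append(hit)
    return sorted(kept, key=lambda h: h.ali_start)


def identify_family(
    domain_hits: Iterable[DomainHit],
    evalue_max: float = 0.001,
    min_domains: int = 2,
    max_domains: int = 2,
) -> list[FamilyCall]:
    """Call family membership from per-domain hits.

    A gene is a member iff, after dropping hits with e-value >=
    ``evalue_max`` and merging overlapping hits, its domain count lies in
    [min_domains, max_domains].  With the defaults this is the
    exactly-two-repeats rule that separates R2R3-MYBs from 1R and 3R
    proteins.  One call is returned for every gene with at least one hit
    (significant or not), sorted by gene_id.
    """
    by_gene: dict[str, list[DomainHit]] = {}
    for hit in domain_hits:
        by_gene.setdefault(hit.gene_id, []).append(hit)
    calls = []
    for gene_id in sorted(by_gene):
        significant = [h for h in by_gene[gene_id] if h.evalue < evalue_max]
        merged = _merge_overlapping(significant)
        n = len(merged)
        calls.append(
            FamilyCall(
                gene_id=gene_id,
                n_domains=n,
                domain_evalues=tuple(h.evalue for h in merged),
                is_member=min_domains <= n <= max_domains,
            )
        )
    return calls


@dataclasses.dataclass(frozen=True)
class MotifProfile:
    """Per-column residue frequencies and information content of an
    alignment, the data behind a sequence logo.

    ``frequencies`` has shape (n_columns, 20) in AMINO_ACIDS order; rows
    sum to 1 over non-gap residues.  ``bits`` is log2(20) minus the
    column Shannon entropy, so 0 (uniform) .. log2(20) (invariant).
    All-gap columns carry NaN frequencies and NaN bits.
    """

    frequencies: np.ndarray
    bits: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.frequencies.shape[0]

    def modal_residue(self, column: int) -> str | None:
        """Most frequent residue of a column; ties broken alphabetically;
        None for all-gap columns."""
        col = self.frequencies[column]
        if np.isnan(col).any():
            return None
        return AMINO_ACIDS[int(np.argmax(col))]  # argmax takes first = alphabetic


def motif_profile(aligned_sequences: Sequence[str]) -> MotifProfile:
    """Column-wise frequency/conservation profile of a protein alignment.

    Gaps ('-' or '.') are excluded from the denominator of each column.
    """
    if not aligned_sequences:
        raise ValueError("empty alignment")
    length = len(aligned_sequences[0])
    for seq in aligned_sequences:
        if len(seq) != length:
            raise ValueError(
                f"aligned sequences must have equal length ({len(seq)} != {length})"
            )
    freqs = np.zeros((length, 20))
    bits = np.zeros(length)
    for j in range(length):
        counts = np.zeros(20)
        for seq in aligned_sequences:
            ch = seq[j].upper()
            if ch in ("-", "."):
                continue
            if ch not in _AA_INDEX:
                raise ValueError(f"unknown residue {ch!r} at column {j}")
            counts[_AA_INDEX[ch]] += 1
        total = counts.sum()
        if total == 0:
            freqs[j] = np.nan
            bits[j] = np.nan
            continue
        p = counts / total
        nz = p[p > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        freqs[j] = p
        bits[j] = MAX_BITS - entropy
    return MotifProfile(frequencies=freqs, bits=bits)


def compare_profiles(profile_a: MotifProfile, profile_b: MotifProfile) -> list[int]:
    """0-based column positions where the modal residue differs.

    Columns that are all-gap in either profile are incomparable and
    excluded.
    """
    if profile_a.n_columns != profile_b.n_columns:
        raise ValueError(
            f"profiles have {profile_a.n_columns} vs {profile_b.n_columns} columns"
        )
    diffs = []
    for j in range(profile_a.n_columns):
        ra, rb = profile_a.modal_residue(j), profile_b.modal_residue(j)
        if ra is None or rb is None:
            continue
        if ra != rb:
            diffs.append(j)
    return diffs
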