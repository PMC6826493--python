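"""Pairwise Ka/Ks estimation by the Nei–Gojobori (1986) counting method
with Jukes–Cantor correction, plus selection classification and an
all-vs-all family scan.

Per codon, each site contributes a synonymous fraction equal to the
proportion of possible single-nucleotide changes (mutations to stop
codons excluded from consideration) that preserve the amino acid; the
synonymous and nonsynonymous site totals therefore sum to 3 per codon.
Observed differences in codons differing at several positions are split
by averaging over all minimal mutational pathways (orderings of the
single changes), skipping pathways through stop codons.  Proportions are
corrected for multiple hits with d = -(3/4) ln(1 - (4/3) p).
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "codon_align",
    "ng86",
    "classify_selection",
    "family_pair_scan",
]

_BASES = "TCAG"
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
CODON_TABLE: dict[str, str] = dict(zip(_CODONS, _AA))
STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")


def _syn_fraction(codon: str) -> float:
    """Synonymous site count of one codon (sum of per-position synonymous
    change fractions, stop-codon targets excluded)."""
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = counted = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            counted += 1
            if CODON_TABLE[alt] == aa:
                syn += 1
        if counted:
            s += syn / counted
    return s


_SYN_SITES = {c: _syn_fraction(c) for c in _CODONS if c not in STOP_CODONS}


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons,
    averaged over all minimal mutational pathways.

    Pathways passing through a stop codon are skipped; if every pathway
    is blocked, all are used with stop steps counted as nonsynonymous.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        cur = c1
        syn = non = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        return syn, non

    paths = [walk(order, False) for order in itertools.permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:
        valid = [walk(order, True) for order in itertools.permutations(diff_pos)]
    syn = sum(p[0] for p in valid) / len(valid)
    non = sum(p[1] for p in valid) / len(valid)
    return syn, non


@dataclasses.dataclass(frozen=True)
class CodonAlignment:
    """A pair of aligned CDS strings: length divisible by 3, gaps in
    whole codons, no internal stop codons."""

    cds_a: str
    cds_b: str

    def __post_init__(self) -> None:
        if len(self.cds_a) != len(self.cds_b):
            raise ValueError("aligned CDS must have equal length")
        if len(self.cds_a) % 3:
            raise ValueError("alignment length must be divisible by 3")
        for seq in (self.cds_a, self.cds_b):
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3].upper()
                if "-" in codon and codon != "---":
                    raise ValueError(f"partial codon gap at {i}: {codon}")
                if codon in STOP_CODONS:
                    raise ValueError(f"internal stop codon at position {i}")

    def codon_pairs(self) -> list[tuple[str, str]]:
        """Comparable (ungapped, unambiguous) codon pairs."""
        pairs = []
        for i in range(0, len(self.cds_a), 3):
            ca = self.cds_a[i : i + 3].upper()
            cb = self.cds_b[i : i + 3].upper()
            if ca in _SYN_SITES and cb in _SYN_SITES:
                pairs.append((ca, cb))
        return pairs


@dataclasses.dataclass(frozen=True)
class KaKsResult:
    ka: float  # NaN when saturated
    ks: float  # NaN when saturated
    ratio: float  # NaN when undefined (Ks == 0 or saturation)
    selection: str  # positive | negative | neutral | undefined
    n_codons: int
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float


def translate(cds: str) -> str:
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        aa = CODON_TABLE.get(codon)
        if aa is None:
            raise ValueError(f"unknown codon {codon!r} at position {i}")
        aas.append(aa)
    return "".join(aas)


def codon_align(
    protein_alignment: tuple[str, str], cds_a: str, cds_b: str
) -> CodonAlignment:
    """Back-translate an aligned protein pair onto its CDS pair.

    Protein gaps become '---' codons; a trailing stop codon on either
    CDS is trimmed; a codon that does not translate to the aligned
    residue raises an error naming the first discordant codon.
    """
    out = []
    for prot, cds in zip(protein_alignment, (cds_a, cds_b)):
        cds = cds.upper()
        if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        aligned = []
        pos = 0
        for col, residue in enumerate(prot):
            if residue == "-":
                aligned.append("---")
                continue
            codon = cds[pos : pos + 3]
            if len(codon) < 3:
                raise ValueError(f"CDS too short for protein at column {col}")
            aa = CODON_TABLE.get(codon)
            if aa == "*":
                raise ValueError(f"internal stop codon {codon} at column {col}")
            if aa != residue.upper():
                raise ValueError(
                    f"codon {codon} at column {col} translates to {aa}, "
                    f"alignment says {residue}"
                )
            aligned.append(codon)
            pos += 3
        if pos != len(cds):
            raise ValueError(f"CDS has {len(cds) - pos} unaligned trailing bases")
        out.append("".join(aligned))
    return CodonAlignment(out[0], out[1])


def _jc_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction; NaN when saturated."""
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86(alignment: CodonAlignment) -> KaKsResult:
    """Nei–Gojobori Ka/Ks for one aligned CDS pair."""
    pairs = alignment.codon_pairs()
    if not pairs:
        raise ValueError("no comparable codon pairs")
    syn_sites = sum(0.5 * (_SYN_SITES[a] + _SYN_SITES[b]) for a, b in pairs)
    nonsyn_sites = 3 * len(pairs) - syn_sites
    syn_d = nonsyn_d = 0.0
    for a, b in pairs:
        s, n = _pathway_counts(a, b)
        syn_d += s
        nonsyn_d += n
    ps = syn_d / syn_sites if syn_sites > 0 else 0.0
    pn = nonsyn_d / nonsyn_sites if nonsyn_sites > 0 else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    if math.isnan(ka) or math.isnan(ks) or ks == 0.0:
        ratio = math.nan
    else:
        ratio = ka / ks
    result = KaKsResult(
        ka=ka, ks=ks, ratio=ratio, selection="",
        n_codons=len(pairs), syn_sites=syn_sites, nonsyn_sites=nonsyn_sites,
        syn_diffs=syn_d, nonsyn_diffs=nonsyn_d,
    )
    return dataclasses.replace(result, selection=classify_selection(result))


def classify_selection(result: KaKsResult) -> str:
    """positive (Ka/Ks > 1), negative (< 1), neutral (= 1 within 1e-9)
    or undefined (Ks = 0 or saturation)."""
    if math.isnan(result.ratio):
        return "undefined"
    if abs(result.ratio - 1.0) <= 1e-9:
        return "neutral"
    return "positive" if result.ratio > 1.0 else "negative"


def family_pair_scan(
    family_a: Sequence[str],
    family_b: Sequence[str],
    alignments: Mapping[tuple[str, str], CodonAlignment],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """All-vs-all Ka/Ks scan between two gene families.

    ``alignments`` maps (gene_a, gene_b) to codon alignments; pairs with
    no alignment are skipped.  The summary reports, over pairs with
    defined (unsaturated) Ka and Ks, the count and fractions under
    purifying (<1), positive (>1) and neutral (=1) selection, plus the
    count of undefined pairs excluded from those denominators.
    """
    rows = []
    for ga in family_a:
        for gb in family_b:
            aln = alignments.get((ga, gb)) or alignments.get((gb, ga))
            if aln is None:
                continue
            res = ng86(aln)
            rows.append(
                {
                    "gene_a": ga, "gene_b": gb,
                    "ka": res.ka, "ks": res.ks, "ratio": res.ratio,
                    "selection": res.selection,
                }
            )
    table = pd.DataFrame(rows)
    defined = table[table["selection"] != "undefined"] if len(table) else table
    n_def = len(defined)
    summary = {
        "n_pairs": float(len(table)),
        "n_defined": float(n_def),
        "n_undefined": float(len(table) - n_def),
        "frac_purifying": (defined["selection"] == "negative").mean() if n_def else math.nan,
        "frac_positive": (defined["selection"] == "positive").mean() if n_def else math.nan,
        "frac_neutral": (defined["selection"] == "neutral").mean() if n_def else math.nan,
    }
    return table, summary
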