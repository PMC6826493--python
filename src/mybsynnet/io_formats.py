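"""Readers and writers for the external formats the pipeline touches.

All synteny mathematics downstream works on integer gene *ranks* (order
indices along a chromosome); base-pair coordinates are kept 1-based
inclusive as in GFF3 and never used beyond rank assignment.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

__all__ = [
    "Gene",
    "GenomeRegistry",
    "HomologyHit",
    "DomainHit",
    "read_gff_genes",
    "read_homology_table",
    "read_domain_hits",
    "read_edgelist",
    "write_edgelist",
    "read_fasta",
    "write_fasta",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclasses.dataclass(frozen=True)
class Gene:
    """A located gene model.

    ``rank`` is the 0-based order index of the gene along its chromosome
    (sorted by ascending start, ties broken by gene_id); it is the
    coordinate system of all collinearity computations.
    """

    gene_id: str
    species: str
    chrom: str
    start: int
    end: int
    strand: str
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


CLADES = frozenset(
    {"monocot", "rosid", "asterid", "basal_eudicot", "basal_angiosperm"}
)


class GenomeRegistry:
    """All genomes under analysis, each annotated with a clade label.

    Clades follow the usual angiosperm partition: monocots, rosids,
    asterids, basal eudicots and basal angiosperms.
    """

    def __init__(self) -> None:
        self._species: dict[str, str] = {}  # species -> clade
        self._genes: dict[str, Gene] = {}  # gene_id -> Gene
        self._by_species: dict[str, list[Gene]] = {}

    def add_species(self, species: str, clade: str, genes: Iterable[Gene]) -> None:
        if clade not in CLADES:
            raise ValueError(f"unknown clade {clade!r}; expected one of {sorted(CLADES)}")
        if species in self._species:
            raise ValueError(f"species {species!r} already registered")
        genes = list(genes)
        for g in genes:
            if g.species != species:
                raise ValueError(f"gene {g.gene_id} belongs to {g.species}, not {species}")
            if g.gene_id in self._genes:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
        genes = assign_ranks(genes)
        for g in genes:
            self._genes[g.gene_id] = g
        self._species[species] = clade
        self._by_species[species] = genes

    @property
    def species(self) -> list[str]:
        return sorted(self._species)

    def clade(self, species: str) -> str:
        return self._species[species]

    def genes_of(self, species: str) -> list[Gene]:
        return list(self._by_species[species])

    def gene(self, gene_id: str) -> Gene:
        try:
            return self._genes[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in registry") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __len__(self) -> int:
        return len(self._genes)

    def chromosome(self, species: str, chrom: str) -> list[Gene]:
        """Genes of one chromosome in rank order."""
        genes = [g for g in self._by_species[species] if g.chrom == chrom]
        return sorted(genes, key=lambda g: g.rank)


@dataclasses.dataclass(frozen=True)
class HomologyHit:
    """One row of an all-against-all protein similarity search."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float


@dataclasses.dataclass(frozen=True)
class DomainHit:
    """One per-domain row of a profile-HMM scan (e.g. the MYB DNA-binding
    domain PF00249); coordinates are 1-based inclusive on the protein."""

    gene_id: str
    domain_acc: str
    evalue: float
    ali_start: int
    ali_end: int

    def __post_init__(self) -> None:
        if self.ali_start > self.ali_end:
            raise ValueError(
                f"{self.gene_id}: ali_start {self.ali_start} > ali_end {self.ali_end}"
            )


def assign_ranks(genes: Iterable[Gene]) -> list[Gene]:
    """Assign 0..n-1 ranks per chromosome by ascending start.

    Ties on start are broken by gene_id so ranking is deterministic.
    Strand is ignored: a minus-strand gene is ranked by its start
    coordinate like any other.
    """
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list[Gene] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        for rank, g in enumerate(ordered):
            out.append(dataclasses.replace(g, rank=rank))
    return out


def read_gff_genes(path: str | Path, feature_type: str = "gene",
                   species: str | None = None) -> list[Gene]:
    """Read gene models from a GFF3 file and assign chromosome ranks.

    Coordinates stay 1-based inclusive as in the file.  ``species``
    defaults to the file stem.
    """
    path = Path(path)
    if species is None:
        species = path.stem.split(".")[0]
    genes: list[Gene] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype != feature_type:
                continue
            gene_id = None
            for item in attrs.split(";"):
                item = item.strip()
                if item.startswith("ID="):
                    gene_id = item[3:]
                    break
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: missing ID attribute")
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            genes.append(
                Gene(gene_id=gene_id, species=species, chrom=chrom,
                     start=int(start), end=int(end), strand=strand)
            )
    return assign_ranks(genes)


def read_homology_table(path: str | Path, max_evalue: float = 10.0) -> list[HomologyHit]:
    """Read a 12-column blast-style tabular hit file.

    Columns 1, 2, 11, 12 are query, subject, e-value and bitscore.
    Self-hits and hits above ``max_evalue`` are dropped.
    """
    hits: list[HomologyHit] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            query, subject = fields[0], fields[1]
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric e-value/bitscore") from exc
            if query == subject:
                continue
            if evalue > max_evalue:
                continue
            hits.append(HomologyHit(query, subject, evalue, bitscore))
    return hits


# hmmscan --domtblout column indices (0-based, whitespace-delimited)
_DOM_ACC, _DOM_QUERY, _DOM_IEVALUE, _DOM_ALIFROM, _DOM_ALITO = 1, 3, 12, 17, 18


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    """Read a per-domain hit table in hmmscan ``--domtblout`` layout.

    Lines starting with '#' are comments.  The independent e-value
    (i-E-value) column is used as the hit e-value.
    """
    hits: list[DomainHit] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) <= _DOM_ALITO:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {_DOM_ALITO + 1} columns"
                )
            try:
                start = int(fields[_DOM_ALIFROM])
                end = int(fields[_DOM_ALITO])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: alignment coordinates must be integers"
                ) from exc
            hits.append(
                DomainHit(
                    gene_id=fields[_DOM_QUERY],
                    domain_acc=fields[_DOM_ACC],
                    evalue=float(fields[_DOM_IEVALUE]),
                    ali_start=start,
                    ali_end=end,
                )
            )
    return hits


_EDGE_HEADER = ("Locus_1", "Locus_2")


def write_edgelist(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write an edge list as two-column TSV with Locus_1/Locus_2 headers.

    Edges are written as unordered pairs in canonical (sorted) node order,
    deduplicated, sorted lexicographically — byte-identical across runs.
    """
    canon = sorted({tuple(sorted(e)) for e in edges})
    with open(path, "w") as fh:
        fh.write("\t".join(_EDGE_HEADER) + "\n")
        for a, b in canon:
            fh.write(f"{a}\t{b}\n")


def read_edgelist(path: str | Path) -> set[tuple[str, str]]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _EDGE_HEADER:
            raise FormatError(
                f"{path}: expected header {'/'.join(_EDGE_HEADER)}, got {'/'.join(header)}"
            )
        edges: set[tuple[str, str]] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            a, b = fields
            edges.add((a, b) if a <= b else (b, a))
    return edges


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence dict (order-preserving)."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
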