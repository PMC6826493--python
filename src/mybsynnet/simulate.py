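"""Ground-truthed genome-evolution simulator.

Generates complete input datasets — per-species gene models (GFF3),
protein and CDS FASTA, all-pairs homology hits, per-domain scan rows and
an RNA-seq count table — by evolving an ancestral gene-ordered genome
down a dated species tree:

* whole-genome duplication (WGD) doubles, triplication (WGT) triples,
  every chromosome on the event branch;
* genes are lost independently, tandem duplications insert adjacent
  copies, inversions reverse random rank intervals;
* codon sequences evolve under a per-branch dN/dS (omega): nucleotide
  changes are proposed uniformly and accepted with probabilities whose
  nonsynonymous:synonymous ratio equals omega (stops rejected);
* a configurable subset of lineages are "family" genes (two-domain MYB
  models): they receive two domain-scan rows with significant e-values,
  while decoy background genes receive one (or three) rows.

Everything derives from one seeded generator, so a fixed seed gives
byte-identical output trees.  The answer key (true family membership,
gene lineages = planted synteny clusters, tandem arrays, per-branch
omega, per-branch count bookkeeping) is written as ground_truth.json.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import yaml

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate",
    "make_fixture",
    "FIXTURES",
    "evolve_cds",
    "random_cds",
    "simulated_codon_pair",
]

# nucleotide codes 0..3 = T C A G; codon index = 16 a + 4 b + c
_NT = "TCAG"
_AA64 = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_STOP64 = np.array([aa == "*" for aa in _AA64])
_NONSTOP_CODONS = np.array([i for i in range(64) if not _STOP64[i]])

DEFAULT_SPECIES_TREE = (
    "((mono1:0.10,(mono2:0.08,mono3:0.08)M23:0.04)MONO:0.18,"
    "(bed1:0.24,(((ros1:0.08,ros2:0.08)R12:0.07,"
    "(ros3:0.07,(ros4:0.04,ros5:0.04)R45:0.03)R345:0.08)ROS:0.06,"
    "(ast1:0.12,ast2:0.12)AST:0.12)CORE:0.05)EUD:0.08,"
    "bang1:0.30)ROOT;"
)

DEFAULT_CLADES = {
    "mono1": "monocot", "mono2": "monocot", "mono3": "monocot",
    "ros1": "rosid", "ros2": "rosid", "ros3": "rosid",
    "ros4": "rosid", "ros5": "rosid",
    "ast1": "asterid", "ast2": "asterid",
    "bed1": "basal_eudicot", "bang1": "basal_angiosperm",
}


@dataclasses.dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Rates are per gene per branch (loss, tandem) or expected events per
    branch (inversions); ``rate`` scales nucleotide substitution
    proposals per unit branch length; ``omega_default`` is the
    background dN/dS, overridable per branch.
    """

    species_tree: str = DEFAULT_SPECIES_TREE
    clades: dict[str, str] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLADES)
    )
    events: list[tuple[str, str]] = dataclasses.field(
        default_factory=lambda: [("ros5", "WGD"), ("M23", "WGD")]
    )
    family_gains: list[tuple[str, int]] = dataclasses.field(default_factory=list)
    n_chromosomes: int = 2
    n_background_genes: int = 200
    n_family_genes: int = 8
    n_codons: int = 150
    tandem_dup_rate: float = 0.002
    gene_loss_rate: float = 0.02
    inversion_rate: float = 0.5
    rate: float = 1.0
    omega_default: float = 0.2
    omega_branch: dict[str, float] = dataclasses.field(default_factory=dict)
    evalue_noise: float = 0.5
    decoy_domain_rate: float = 0.05
    focal_species: str = "ros1"
    # the default conditions plant a 7-copy tandem expansion of one
    # family lineage on the focal terminal branch
    planted_tandem: tuple[str, int] | None = ("ros1", 7)
    seed: int = 0

    def validate(self) -> None:
        tree = _parse_tree(self.species_tree)
        labels = _branch_labels(tree)
        for branch, kind in self.events:
            if kind not in ("WGD", "WGT"):
                raise ValueError(f"unknown event type {kind!r}")
            if branch not in labels:
                raise ValueError(
                    f"event {kind} on absent branch {branch!r}; known: {sorted(labels)}"
                )
        for branch, n in self.family_gains:
            if branch not in labels:
                raise ValueError(f"family gain on absent branch {branch!r}")
            if n < 1:
                raise ValueError("family gain count must be >= 1")
        leaves = {t.label for t in tree.taxon_namespace}
        unlabeled = leaves - set(self.clades)
        if unlabeled:
            raise ValueError(f"species without clade label: {sorted(unlabeled)}")
        if self.planted_tandem and self.planted_tandem[0] not in leaves:
            raise ValueError(
                f"planted tandem on unknown species {self.planted_tandem[0]!r}"
            )
        for value in (self.tandem_dup_rate, self.gene_loss_rate,
                      self.inversion_rate, self.rate, self.omega_default):
            if value < 0:
                raise ValueError("rates must be >= 0")


@dataclasses.dataclass
class GroundTruth:
    """The simulator's answer key."""

    family_members: dict[str, list[str]]  # species -> family gene ids
    gene_lineage: dict[str, int]  # every gene id -> ancestral lineage
    cluster_labels: dict[str, int]  # family gene id -> planted cluster
    tandem_arrays: list[dict]  # {species, chrom, genes}
    branch_omega: dict[str, float]
    gene_counts: dict[str, int]
    bookkeeping: dict[str, dict]  # species -> {ancestral, branches: [...]}
    expressed_genes: list[str]
    silent_genes: list[str]
    family_lineages: list[int]
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        data["gene_lineage"] = {k: int(v) for k, v in data["gene_lineage"].items()}
        data["cluster_labels"] = {k: int(v) for k, v in data["cluster_labels"].items()}
        return cls(**data)


class _SimGene:
    __slots__ = ("lineage", "seq")

    def __init__(self, lineage: int, seq: np.ndarray):
        self.lineage = lineage
        self.seq = seq

    def copy(self) -> "_SimGene":
        return _SimGene(self.lineage, self.seq.copy())


def _parse_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


def _branch_labels(tree: dendropy.Tree) -> set[str]:
    labels = set()
    for node in tree.preorder_node_iter():
        name = node.taxon.label if node.taxon else node.label
        if name:
            labels.add(name)
    return labels


def random_cds(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    """Random stop-free CDS as an array of nucleotide codes."""
    codons = rng.choice(_NONSTOP_CODONS, size=n_codons)
    seq = np.empty(3 * n_codons, dtype=np.uint8)
    seq[0::3] = codons // 16
    seq[1::3] = (codons // 4) % 4
    seq[2::3] = codons % 4
    return seq


def evolve_cds(
    seq: np.ndarray, t: float, omega: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve a CDS in place for ``t`` expected proposals per site under
    dN/dS = omega; returns the array.

    Proposals are uniform single-nucleotide changes; synonymous changes
    are accepted with probability min(1, 1/omega) and nonsynonymous ones
    with probability min(1, omega), so the fixed nonsynonymous:synonymous
    rate ratio per site equals omega.  Changes creating stop codons are
    always rejected.
    """
    if omega <= 0:
        p_syn, p_non = 1.0, 0.0
    elif omega <= 1:
        p_syn, p_non = 1.0, omega
    else:
        p_syn, p_non = 1.0 / omega, 1.0
    n_prop = rng.poisson(t * seq.size)
    for _ in range(n_prop):
        pos = int(rng.integers(seq.size))
        old = seq[pos]
        new = (old + 1 + rng.integers(3)) % 4
        c0 = 3 * (pos // 3)
        old_codon = 16 * seq[c0] + 4 * seq[c0 + 1] + seq[c0 + 2]
        seq[pos] = new
        new_codon = 16 * seq[c0] + 4 * seq[c0 + 1] + seq[c0 + 2]
        if _STOP64[new_codon]:
            seq[pos] = old
            continue
        accept_p = p_syn if _AA64[new_codon] == _AA64[old_codon] else p_non
        if rng.random() >= accept_p:
            seq[pos] = old
    return seq


def decode_nt(seq: np.ndarray) -> str:
    return "".join(_NT[b] for b in seq)


def decode_aa(seq: np.ndarray) -> str:
    codons = 16 * seq[0::3] + 4 * seq[1::3] + seq[2::3]
    return "".join(_AA64[c] for c in codons)


def simulated_codon_pair(
    n_codons: int, t: float, omega: float, rng: np.random.Generator
) -> tuple[str, str]:
    """A pair of CDS strings diverged for total time ``t`` at dN/dS omega
    (ancestor evolved down two branches of t/2)."""
    anc = random_cds(n_codons, rng)
    a = evolve_cds(anc.copy(), t / 2, omega, rng)
    b = evolve_cds(anc.copy(), t / 2, omega, rng)
    return decode_nt(a), decode_nt(b)


# ---------------------------------------------------------------------------
# branch operations


def _apply_polyploidy(genome: dict[str, list], kind: str) -> None:
    suffixes = ("d",) if kind == "WGD" else ("d", "t")
    for name in list(genome):
        for sfx in suffixes:
            genome[name + sfx] = [g.copy() for g in genome[name]]


def _apply_branch(
    genome: dict[str, list],
    branch: str,
    length: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    lineage_counter: list[int],
    family_lineages: set[int],
) -> dict:
    """Mutate ``genome`` through one branch; returns count bookkeeping."""
    record = {"branch": branch, "mult": 1, "family_gain": 0,
              "tandem_gain": 0, "lost": 0}
    for ev_branch, kind in cfg.events:
        if ev_branch == branch:
            _apply_polyploidy(genome, kind)
            record["mult"] *= 2 if kind == "WGD" else 3
    for gain_branch, count in cfg.family_gains:
        if gain_branch == branch:
            for _ in range(count):
                lin = lineage_counter[0]
                lineage_counter[0] += 1
                family_lineages.add(lin)
                chrom = sorted(genome)[int(rng.integers(len(genome)))]
                pos = int(rng.integers(len(genome[chrom]) + 1))
                genome[chrom].insert(pos, _SimGene(lin, random_cds(cfg.n_codons, rng)))
                record["family_gain"] += 1
    if cfg.tandem_dup_rate > 0:
        for chrom in sorted(genome):
            genes = genome[chrom]
            i = 0
            while i < len(genes):
                if rng.random() < cfg.tandem_dup_rate:
                    genes.insert(i + 1, genes[i].copy())
                    record["tandem_gain"] += 1
                    i += 1  # do not re-duplicate the fresh copy
                i += 1
    if cfg.gene_loss_rate > 0:
        for chrom in sorted(genome):
            keep = []
            for g in genome[chrom]:
                if rng.random() < cfg.gene_loss_rate:
                    record["lost"] += 1
                else:
                    keep.append(g)
            genome[chrom] = keep
    if cfg.inversion_rate > 0:
        for _ in range(rng.poisson(cfg.inversion_rate)):
            names = sorted(genome)
            chrom = names[int(rng.integers(len(names)))]
            genes = genome[chrom]
            if len(genes) < 2:
                continue
            span = min(int(rng.integers(2, 16)), len(genes))
            start = int(rng.integers(0, len(genes) - span + 1))
            genes[start : start + span] = genes[start : start + span][::-1]
    if cfg.planted_tandem and cfg.planted_tandem[0] == branch:
        _, copies = cfg.planted_tandem
        planted = False
        for chrom in sorted(genome):
            for i, g in enumerate(genome[chrom]):
                if g.lineage in family_lineages:
                    for _ in range(copies - 1):
                        genome[chrom].insert(i + 1, g.copy())
                    record["tandem_gain"] += copies - 1
                    planted = True
                    break
            if planted:
                break
        if not planted:
            raise ValueError(f"no family gene left to expand on branch {branch!r}")
    omega = cfg.omega_branch.get(branch, cfg.omega_default)
    t = length * cfg.rate
    if t > 0:
        for chrom in sorted(genome):
            for g in genome[chrom]:
                evolve_cds(g.seq, t, omega, rng)
    return record


# ---------------------------------------------------------------------------
# dataset emission


def _emit_species(
    species: str,
    genome: dict[str, list],
    family_lineages: set[int],
    outdir: Path,
    rng: np.random.Generator,
) -> list[dict]:
    """Write GFF3 + FASTA for one species; returns per-gene records."""
    records = []
    serial = 0
    chrom_names = {name: f"chr{i + 1}" for i, name in enumerate(sorted(genome))}
    gff_lines = ["##gff-version 3"]
    cds_fa, prot_fa = [], []
    for name in sorted(genome):
        chrom = chrom_names[name]
        for rank, g in enumerate(genome[name]):
            gid = f"{species}g{serial:04d}"
            serial += 1
            start = rank * 1000 + 1
            end = start + g.seq.size - 1
            strand = "+" if rng.random() < 0.5 else "-"
            gff_lines.append(
                f"{chrom}\tsim\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}"
            )
            cds_fa.append((gid, decode_nt(g.seq)))
            prot_fa.append((gid, decode_aa(g.seq)))
            records.append(
                {
                    "gene_id": gid, "species": species, "chrom": chrom,
                    "rank": rank, "lineage": g.lineage,
                    "family": g.lineage in family_lineages, "seq": g.seq,
                }
            )
    (outdir / f"{species}.gff3").write_text("\n".join(gff_lines) + "\n")
    _write_fasta(cds_fa, outdir / f"{species}.cds.fasta")
    _write_fasta(prot_fa, outdir / f"{species}.pep.fasta")
    return records


def _write_fasta(entries: list[tuple[str, str]], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _emit_homology(
    all_genes: list[dict], outdir: Path, cfg: SimConfig, rng: np.random.Generator
) -> None:
    """All-pairs tabular hits between genes sharing an ancestral lineage.

    E-values are log-linear in sequence identity with Gaussian noise;
    only their ordering matters downstream.
    """
    by_lineage: dict[int, list[dict]] = {}
    for rec in all_genes:
        by_lineage.setdefault(rec["lineage"], []).append(rec)
    lines = []
    for lineage in sorted(by_lineage):
        members = by_lineage[lineage]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                ident = float((a["seq"] == b["seq"]).mean())
                eps = rng.normal(0.0, cfg.evalue_noise)
                evalue = 10.0 ** (-(2.0 + 20.0 * ident) + eps)
                bits = round(500.0 * ident + rng.normal(0.0, 5.0), 1)
                L = a["seq"].size
                nid = int(round(ident * L))
                for q, s in ((a, b), (b, a)):
                    lines.append(
                        f"{q['gene_id']}\t{s['gene_id']}\t{100 * ident:.2f}\t{L}"
                        f"\t{L - nid}\t0\t1\t{L}\t1\t{L}\t{evalue:.3e}\t{bits}"
                    )
    (outdir / "homology.tsv").write_text("\n".join(lines) + "\n")


_DOMTBL_FMT = (
    "Myb_DNA-binding      PF00249.31  46 {gene:<20} - {qlen:>5} "
    "{ev:.1e} {score:.1f} 0.1 {num} {of} {ev:.1e} {ev:.1e} {score:.1f} 0.1 "
    "1 46 {alifrom} {alito} {alifrom} {alito} 0.95 -"
)


def _emit_domains(
    all_genes: list[dict], outdir: Path, cfg: SimConfig, rng: np.random.Generator
) -> None:
    """Per-domain rows: two significant MYB-repeat hits per family gene,
    one weak hit for a fraction of background decoys, and an occasional
    three-repeat decoy (a 3R-type model that must not be called R2R3)."""
    lines = [
        "# simulated domain scan (hmmscan --domtblout layout)",
        "#",
    ]
    for rec in all_genes:
        qlen = rec["seq"].size // 3
        if rec["family"]:
            coords = ((10, 61), (62, 113))
            evs = 10.0 ** (-rng.uniform(6.0, 20.0, size=2))
            for k, ((a, b), ev) in enumerate(zip(coords, evs), start=1):
                lines.append(
                    _DOMTBL_FMT.format(
                        gene=rec["gene_id"], qlen=qlen, ev=ev,
                        score=60.0 - 2 * k, num=k, of=2, alifrom=a, alito=b,
                    )
                )
        else:
            u = rng.random()
            if u < cfg.decoy_domain_rate:
                ev = 10.0 ** (-rng.uniform(4.0, 8.0))
                lines.append(
                    _DOMTBL_FMT.format(
                        gene=rec["gene_id"], qlen=qlen, ev=ev, score=20.0,
                        num=1, of=1, alifrom=10, alito=61,
                    )
                )
            elif u < cfg.decoy_domain_rate + 0.005:
                for k, (a, b) in enumerate(((5, 56), (57, 108), (109, 145)), start=1):
                    ev = 10.0 ** (-rng.uniform(6.0, 12.0))
                    lines.append(
                        _DOMTBL_FMT.format(
                            gene=rec["gene_id"], qlen=qlen, ev=ev, score=40.0,
                            num=k, of=3, alifrom=a, alito=b,
                        )
                    )
    (outdir / "domains.tsv").write_text("\n".join(lines) + "\n")


_SAMPLES = ("FB_GP", "FB_CP", "FB_PP", "OF_PP", "root", "leaf", "stamen", "pistil")


def _emit_counts(
    all_genes: list[dict], outdir: Path, cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Negative-binomial counts around planted tissue profiles for the
    focal species' family genes; returns (expressed, silent) gene ids."""
    fam = [r for r in all_genes
           if r["species"] == cfg.focal_species and r["family"]]
    expressed, silent = [], []
    rows = []
    for rec in fam:
        gid = rec["gene_id"]
        if rng.random() < 0.15:
            silent.append(gid)
            mu = np.zeros(len(_SAMPLES))
        else:
            expressed.append(gid)
            base = 10.0 ** rng.normal(1.5, 0.4)
            mu = base * 10.0 ** rng.normal(0.0, 0.4, size=len(_SAMPLES))
        counts = np.where(
            mu > 0, rng.negative_binomial(10, 10.0 / (10.0 + mu)), 0
        )
        rows.append((gid, rec["seq"].size, counts))
    header = "gene_id\tlength\t" + "\t".join(_SAMPLES)
    lines = [header]
    for gid, length, counts in rows:
        lines.append(f"{gid}\t{length}\t" + "\t".join(str(int(c)) for c in counts))
    (outdir / "counts.tsv").write_text("\n".join(lines) + "\n")
    totals = np.array([sum(r[2][k] for r in rows) for k in range(len(_SAMPLES))])
    totals = totals * 50 + 1_000_000
    with open(outdir / "totals.tsv", "w") as fh:
        fh.write("sample\ttotal\n")
        for s, t in zip(_SAMPLES, totals):
            fh.write(f"{s}\t{int(t)}\n")
    return expressed, silent


def _truth_tandem_arrays(all_genes: list[dict]) -> list[dict]:
    """Maximal runs (rank-adjacent, length >= 2) of family genes sharing
    one lineage — the planted tandem arrays."""
    arrays = []
    by_chrom: dict[tuple[str, str], list[dict]] = {}
    for rec in all_genes:
        by_chrom.setdefault((rec["species"], rec["chrom"]), []).append(rec)
    for (sp, chrom) in sorted(by_chrom):
        genes = sorted(by_chrom[(sp, chrom)], key=lambda r: r["rank"])
        run: list[dict] = []
        for rec in genes:
            ok = (
                rec["family"]
                and run
                and rec["lineage"] == run[-1]["lineage"]
                and rec["rank"] == run[-1]["rank"] + 1
            )
            if ok:
                run.append(rec)
                continue
            if len(run) >= 2:
                arrays.append(
                    {"species": sp, "chrom": chrom,
                     "genes": [r["gene_id"] for r in run]}
                )
            run = [rec] if rec["family"] else []
        if len(run) >= 2:
            arrays.append(
                {"species": sp, "chrom": chrom,
                 "genes": [r["gene_id"] for r in run]}
            )
    return arrays


def simulate(config: SimConfig, outdir: str | Path) -> GroundTruth:
    """Run the simulation and write the full dataset under ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    tree = _parse_tree(config.species_tree)

    # ancestral genome: background genes with family lineages interleaved
    # at even spacing (so planted families never abut by accident)
    n_chrom = config.n_chromosomes
    per_chrom = config.n_background_genes // n_chrom
    lineage_counter = [0]
    family_lineages: set[int] = set()
    genome: dict[str, list] = {}
    fam_per_chrom = [
        config.n_family_genes // n_chrom + (1 if c < config.n_family_genes % n_chrom else 0)
        for c in range(n_chrom)
    ]
    for c in range(n_chrom):
        genes = []
        for _ in range(per_chrom):
            genes.append(_SimGene(lineage_counter[0], random_cds(config.n_codons, rng)))
            lineage_counter[0] += 1
        step = per_chrom // (fam_per_chrom[c] + 1) if fam_per_chrom[c] else per_chrom
        for k in range(fam_per_chrom[c]):
            lin = lineage_counter[0]
            lineage_counter[0] += 1
            family_lineages.add(lin)
            pos = (k + 1) * step + k
            genes.insert(min(pos, len(genes)), _SimGene(lin, random_cds(config.n_codons, rng)))
        genome[f"c{c + 1}"] = genes
    ancestral_count = sum(len(g) for g in genome.values())

    # evolve down the tree (preorder, children in newick order)
    leaf_data: dict[str, tuple[dict[str, list], list[dict]]] = {}

    def recurse(node: dendropy.Node, g: dict[str, list], path: list[dict]) -> None:
        for child in node.child_nodes():
            branch = child.taxon.label if child.taxon else child.label
            sub = {name: [x.copy() for x in genes] for name, genes in g.items()}
            rec = _apply_branch(
                sub, branch, child.edge.length or 0.0, config, rng,
                lineage_counter, family_lineages,
            )
            sub_path = path + [rec]
            if child.is_leaf():
                leaf_data[branch] = (sub, sub_path)
            else:
                recurse(child, sub, sub_path)

    recurse(tree.seed_node, genome, [])

    all_genes: list[dict] = []
    bookkeeping: dict[str, dict] = {}
    family_members: dict[str, list[str]] = {}
    gene_counts: dict[str, int] = {}
    for species in sorted(leaf_data):
        leaf_genome, path = leaf_data[species]
        recs = _emit_species(species, leaf_genome, family_lineages, outdir, rng)
        all_genes.extend(recs)
        bookkeeping[species] = {"ancestral": ancestral_count, "branches": path}
        family_members[species] = [r["gene_id"] for r in recs if r["family"]]
        gene_counts[species] = len(recs)

    _emit_homology(all_genes, outdir, config, rng)
    _emit_domains(all_genes, outdir, config, rng)
    expressed, silent = _emit_counts(all_genes, outdir, config, rng)

    with open(outdir / "clades.yaml", "w") as fh:
        yaml.safe_dump(
            {"clades": config.clades, "species_tree": config.species_tree},
            fh, sort_keys=True,
        )
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=True)

    branch_omega = {}
    for node in tree.preorder_node_iter():
        name = node.taxon.label if node.taxon else node.label
        if name and node.parent_node is not None:
            branch_omega[name] = config.omega_branch.get(name, config.omega_default)

    truth = GroundTruth(
        family_members=family_members,
        gene_lineage={r["gene_id"]: r["lineage"] for r in all_genes},
        cluster_labels={
            r["gene_id"]: r["lineage"] for r in all_genes if r["family"]
        },
        tandem_arrays=_truth_tandem_arrays(all_genes),
        branch_omega=branch_omega,
        gene_counts=gene_counts,
        bookkeeping=bookkeeping,
        expressed_genes=expressed,
        silent_genes=silent,
        family_lineages=sorted(family_lineages),
        seed=config.seed,
    )
    truth.to_json(outdir / "ground_truth.json")
    return truth


def _config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["events"] = [list(e) for e in d["events"]]
    d["family_gains"] = [list(e) for e in d["family_gains"]]
    if d["planted_tandem"] is not None:
        d["planted_tandem"] = list(d["planted_tandem"])
    return d


# ---------------------------------------------------------------------------
# fixture registry

_TWO_CLADE_TREE = (
    "((mA:0.10,mB:0.10)MONO:0.12,(rA:0.10,rB:0.10)ROSID:0.12)ROOT;"
)
_TWO_CLADE_CLADES = {
    "mA": "monocot", "mB": "monocot", "rA": "rosid", "rB": "rosid",
}


def _null_config(**overrides) -> SimConfig:
    base = dict(
        species_tree=_TWO_CLADE_TREE,
        clades=dict(_TWO_CLADE_CLADES),
        events=[],
        n_chromosomes=2,
        n_background_genes=100,
        n_family_genes=6,
        tandem_dup_rate=0.0,
        gene_loss_rate=0.0,
        inversion_rate=0.0,
        focal_species="rA",
        planted_tandem=None,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


FIXTURES: dict[str, "SimConfig"] = {}


def _register_fixtures() -> None:
    FIXTURES["null"] = _null_config()
    FIXTURES["wgd"] = _null_config(events=[("rB", "WGD")], seed=12)
    FIXTURES["tandem7"] = _null_config(planted_tandem=("rA", 7), seed=13)
    # three monocots so a monocot-only lineage can form a 3-clique
    FIXTURES["two_clade"] = _null_config(
        species_tree=(
            "((mA:0.10,(mB:0.08,mC:0.08)MBC:0.04)MONO:0.12,"
            "(rA:0.10,rB:0.10)ROSID:0.12)ROOT;"
        ),
        clades={"mA": "monocot", "mB": "monocot", "mC": "monocot",
                "rA": "rosid", "rB": "rosid"},
        family_gains=[("MONO", 2)], seed=14
    )
    FIXTURES["default"] = SimConfig()


_register_fixtures()


def make_fixture(name: str, outdir: str | Path, seed: int | None = None) -> GroundTruth:
    """Build one of the registered deterministic test datasets."""
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        )
    config = dataclasses.replace(FIXTURES[name])
    if seed is not None:
        config.seed = seed
    return simulate(config, outdir)
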