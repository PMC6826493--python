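# mybsynnet

Phylogenomic synteny-network analysis of the plant **R2R3-MYB**
transcription-factor family, rebuilt as a tested, reusable pipeline and
exercised end-to-end on simulated genomes with a known answer key.

R2R3-MYBs — proteins with exactly two tandem MYB DNA-binding repeats
(R2, R3) — form one of the largest plant transcription-factor families
and regulate much of phenylpropanoid metabolism (flower color and
fragrance among other traits). Classifying family members by *synteny*
(conserved local gene order across genomes) rather than by sequence
similarity alone separates lineage-specific expansions from deeply
conserved positional orthologs. The pipeline covers:

1. **Family identification** — exactly two non-overlapping MYB-domain
   hits at *e* < 0.001 in a profile-HMM scan (1R and 3R models rejected).
2. **Collinear blocks** — MCScanX-style anchor chaining in gene-rank
   coordinates: ≥ 5 collinear anchors per block, ≤ 25 intervening genes
   between consecutive anchors, forward and inverted orientations,
   all-vs-all genome pairs including self-comparisons.
3. **Synteny network** — nodes are family genes, edges are family-family
   anchor pairs inside blocks; communities by *k*-clique percolation
   (*k* = 3, `CPM`); isolated syntenic pairs reported separately.
4. **Lineage categories and profiling** — each cluster is classed as
   angiosperm-wide, eudicot-, monocot-, rosid-, asterid- or
   species-specific; the cluster × species count matrix is clustered by
   Jaccard dissimilarity + Ward linkage.
5. **Tandem arrays** — runs of family genes separated by at most 5
   non-family genes on one chromosome.
6. **Phylogeny** — Poisson-corrected distances d = −ln(1 − p),
   neighbor joining, column-bootstrap supports, and subgroup assignment
   of unlabeled genes against a reference-annotated species (smallest
   enclosing clade with ≥ 50% support and a single reference subgroup).
7. **Ka/Ks** — Nei–Gojobori (1986) counting with equal-weight pathway
   averaging and Jukes–Cantor correction; Ka/Ks > 1 positive, < 1
   purifying, = 1 neutral.
8. **Expression** — FPKM = count·10⁹ / (length·total), expressed-gene
   detection, 2^−ΔΔCq relative qPCR expression, stage-trend concordance.

Because the original 35-genome dataset is far beyond desk scale, the
package ships a **genome-evolution simulator** (`mybsynnet.simulate`)
that emits complete input datasets — GFF3 gene models, protein/CDS
FASTA, homology and domain-hit tables, RNA-seq counts — by evolving an
ancestral genome down a species tree with whole-genome duplications,
gene loss, tandem duplication, inversions and per-branch dN/dS, together
with a `ground_truth.json` answer key. Every stage is validated against
that truth and against brute-force oracles.

## Worked example

```bash
python analysis/01_simulate.py          # 12 species, 2 WGDs, 7-gene tandem
python analysis/02_identify_family.py
python analysis/03_collinearity.py
python analysis/04_network_clusters.py
python analysis/05_phylogeny.py
python analysis/06_kaks.py
python analysis/07_expression.py
python analysis/08_reported_identities.py
```

prints (seed 0):

```
species: 12; genes: 2915
planted family members: 119 in 8 lineages
called 119 family members (119 of 119 planted; 0 false calls)
276 blocks (8 intra-genome) over 70 genome pairs
8 clusters ({'angiosperm_wide': 8})
planted-cluster recovery ARI: 0.9303
tandem arrays: 1 (sizes [7])
8 syntelog pairs (8 with defined rates): purifying 100.00%, ...
11/14 family genes detected as expressed
```

All eight planted family lineages come back as distinct clique-
percolation clusters (adjusted Rand index 0.93 over the 119 planted
family genes — the shortfall is the near-identical tandem copies, which
lack cross-species synteny edges of their own); the planted 7-gene
tandem array is recovered exactly; all syntelog pairs between the two
focal rosids show Ka/Ks well below 1, matching the simulated purifying
regime (dN/dS = 0.2). Small result tables land under `results/`, bulky
intermediate data under `scratch/`.

The same stages are scriptable through a CLI
(`mybsynnet simulate|identify|synteny|network|cluster|profile|tandem|phylo|kaks|expression|run-all`)
driven by a YAML config; every stage writes a manifest with its
parameters and input hashes, and seeded reruns are byte-identical.

## Layout

```
src/mybsynnet/     library: io_formats, family, collinearity, network,
                   phylogeny, kaks, expression, simulate, pipeline, cli
analysis/          numbered narrative drivers (see worked example)
tests/             pytest suite incl. brute-force oracles and
                   end-to-end acceptance checks
scripts/           acceptance.py
docs/methods.md    models, parameters, design decisions, limitations
```
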