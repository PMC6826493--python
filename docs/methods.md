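# Methods

## Coordinate system

All synteny computation uses gene *ranks*: the 0-based order index of a
gene along its chromosome, assigned by ascending GFF3 start coordinate
with ties broken by gene id. Base-pair coordinates never enter the
collinearity mathematics, so the block parameters below are in gene
units. Strand is stored but ignored for ranking; inverted segments are
handled by the chaining orientation instead.

## Collinear block detection

Anchors are homologous gene pairs. For each query gene only the 5
best-bitscore subjects per target genome are kept (configurable
`top_n`), anchors are deduplicated as unordered pairs keeping the best
e-value, and grouped by chromosome pair. Chains are extracted per
chromosome pair by dynamic programming, run separately for forward
(rank_b strictly increasing) and inverted (strictly decreasing)
orientation, under the classic collinearity-scan contract:

* minimum block size: **5 anchors** (`min_block`);
* maximum gap: **25 intervening genes** between consecutive anchors, in
  *both* genomes (`max_gap`); gap = rank difference − 1.

Chain score is `n_anchors − 0.02 × Σ gaps`. Because the total gap of a
monotone chain is fixed by its endpoints and length, distinct chains can
tie exactly; the selection rule is therefore total: highest score, then
forward before inverted, then the lexicographically smallest
(rank_a, rank_b) sequence. Scores are handled in integer fiftieths so
ties are exact, and the DP reconstructs the lexicographically smallest
optimum (stopping when a net-zero extension would only tie a shorter
prefix). Chains are peeled off best-first; each anchor joins at most one
block. The test suite proves equivalence with exhaustive chain
enumeration on instances of up to 12 anchors.

Self-comparisons exclude the identity diagonal and tandem-adjacent
pairs (|rank_a − rank_b| ≤ 1), so only genuinely duplicated segments
are reported. The per-chromosome-pair canonical anchor orientation means
palindromic duplications that cross the self-diagonal are not searched;
none of the simulated scenarios produce them.

## Family identification

A gene is an R2R3 family member iff, after dropping domain hits with
e-value ≥ 0.001 and merging hits that share protein positions (keeping
the lower e-value), exactly two hits remain. The merge step stops double
reports of one repeat from impersonating two; the exactly-two rule
separates R2R3 from single-repeat (1R) and triple-repeat (3R) models.
How overlapping hits and >2-domain proteins should be treated is not
fixed by convention, so both the overlap rule and the [min, max] domain
counts are explicit parameters.

Motif profiles are per-column amino-acid frequencies over the 20
residues with gaps excluded from the denominator; information content is
log2(20) − H (Shannon entropy, bits), i.e. 0 for a uniform column and
≈ 4.32 for an invariant one. Profile comparison reports columns whose
modal residue differs (ties broken alphabetically; all-gap columns are
incomparable and skipped).

## Synteny network and clustering

Network nodes are family members; an edge joins two family genes
appearing as an anchor pair in any block, with multi-block support
merged onto one edge. Communities are k-clique-percolation communities
(k = 3) via networkx; 2-node connected components (edges in no
triangle) are reported separately as residual syntenic pairs, because
CPM can never include them. A brute-force oracle (triangles unioned
through shared edges) fixes the semantics in the tests. Cluster ids are
assigned in decreasing size order with ties by smallest member id, so
numbering is deterministic but run-specific.

Category rules, applied to the set of member species and their clades:
one species → species-specific; all monocot / all rosid / all asterid
(>1 species) → the clade-specific label; clades within
{rosid, asterid, basal eudicot} → eudicot-specific; anything spanning a
monocot or basal angiosperm *and* a eudicot → angiosperm-wide. The
angiosperm-wide label is deliberately clade-spanning rather than
requiring presence in every species; with 35 genomes the two readings
coincide for deeply conserved clusters, and the clade-spanning rule is
robust to single-genome absences.

The phylogenetic profile is the cluster × species count matrix (row
sums = cluster sizes). Dissimilarity between clusters is Jaccard on
*presence/absence* of species (scale-invariant; counts would conflate
copy number with spread), then Ward agglomeration; the dendrogram is
exported as Newick with deterministic leaf order.

Tandem arrays are maximal runs of ≥ 2 family genes with ≤ `max_spacer`
(default 5) intervening non-family genes. No published spacer threshold
exists for "tandemly distributed"; 5 genes is tight enough that the
simulator's planted arrays are the only runs detected at the default
family spacing (~25 background genes between planted family loci).

## Phylogeny

Pairwise Poisson-corrected distances d = −ln(1 − p), with p the
mismatch proportion over columns where both sequences are ungapped
(pairwise deletion; complete deletion available). p ≥ 1 − 1/e would
make d ≥ 1 undefined/explosive, so such pairs are clipped to d = 3.0
with a warning — unrelated families are routinely saturated at protein
scale and NJ must stay finite.

Neighbor joining is the standard Saitou–Nei agglomeration with the
usual Q-matrix; ties are broken by the smallest active index pair, and a
negative branch length is clamped to zero with the deficit moved to its
sister branch so path lengths are preserved. The result is unrooted
(trifurcating seed node). On additive matrices the generating topology
and branch lengths are recovered exactly (tested against topology
enumeration at 5 taxa and generating trees up to 10).

Bootstrap resamples alignment columns with replacement, reruns the full
distance + NJ pipeline, and scores each internal edge by the percentage
of replicates containing the same bipartition; deterministic given the
seed.

Subgroup assignment walks from a query leaf toward the seed node and
stops at the first internal node with support ≥ `min_support` (default
50) whose clade contains reference genes: a single reference subgroup
assigns it, a mixture leaves the query unassigned. Clades are read on
the trifurcation-rooted tree. Near-identical paralogs (e.g. fresh
tandem copies) often have no supported local structure and stay
unassigned — the same behaviour real surveys report for genes that "fit
no subgroup".

## Ka/Ks (Nei–Gojobori 1986)

Synonymous site count of a codon = Σ over its three positions of the
fraction of single-nucleotide changes (stop-codon targets excluded from
numerator and denominator) that preserve the amino acid; nonsynonymous
sites = 3 − that, so S + N = 3 per codon exactly. Sites are averaged
over the two sequences. Observed differences at codons differing in
d > 1 positions are split by averaging over all d! substitution orders,
skipping orders that pass through a stop codon (if all are blocked, all
orders are used with stop steps counted as nonsynonymous). Proportions
pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 is reported as saturated (NaN) and
classified "undefined", as is Ks = 0. Classification: ratio > 1
positive, < 1 negative, |ratio − 1| ≤ 1e-9 neutral.

The family scan takes explicit codon alignments (built by
back-translating a protein alignment; gaps become whole-codon gaps,
trailing stops are trimmed). Summary fractions are computed over pairs
with defined, unsaturated Ka and Ks; saturated pairs are counted but
excluded from denominators. In the analysis drivers the pair set is the
focal/reference *syntelog* pairs (network edges) — an all-vs-all scan
between unrelated lineages is dominated by saturation noise.

## Expression

FPKM[g, s] = count × 10⁹ / (length_bp × total mapped fragments).
Expressed-gene detection uses FPKM ≥ 1 in ≥ 1 sample (both inclusive,
both configurable) — there is no canonical threshold, and 1 FPKM is the
field's usual default. 2^−ΔΔCq averages replicate Cq values first, so
the calibrator sample maps to exactly 1. Trend concordance compares the
signs of stage-to-stage changes; zero changes are ties compatible with
either sign, and profiles with no informative step are "mixed" rather
than concordant, to avoid flat-profile artifacts.

## The simulator

`simulate()` evolves an ancestral genome (default: 2 chromosomes,
200 background genes, 8 family lineages interleaved at even spacing —
about 25 background genes between family loci, so planted families
never abut by accident) down a 12-species angiosperm tree spanning
3 monocots, 5 rosids, 2 asterids, a basal eudicot and a basal
angiosperm. Per branch, in order: polyploidy events (WGD copies every
chromosome, WGT twice), family-lineage gains, tandem duplications
(default 0.002/gene), gene losses (0.02/gene), inversions
(Poisson(0.5) events of 2–15 genes), a planted tandem expansion on the
focal terminal branch (7 copies of one family lineage, mirroring the
observed 7-gene tandem cluster), and codon evolution.

Codon evolution proposes uniform single-nucleotide changes at
`rate × branch length` expected proposals per site and accepts
synonymous changes with probability min(1, 1/ω) and nonsynonymous ones
with min(1, ω), rejecting stops — so the fixed nonsynonymous:synonymous
rate ratio per site equals ω (default 0.2, per-branch overridable).
This deliberately matches the site definitions NG86 measures, which is
what makes the recovery test (mean ratio within ±0.05 of 0.2 on
1500-codon genes) a calibration of the estimator rather than of model
mismatch. There are no indels, so within-lineage sequences stay
alignable by construction; real proteins are not, which is why the
alignment step itself is an input, not a claim.

Emitted files use exactly the formats the readers parse: GFF3 with
genes at 1 kb rank spacing (auditable rank ↔ coordinate map), CDS and
protein FASTA, 12-column homology hits for every same-lineage gene pair
(e-value = 10^−(2 + 20·identity) + Gaussian log-noise, both directions;
only the ordering matters downstream), hmmscan-layout domain rows (two
per family gene at e ≤ 1e-6; ~5% of background genes carry one decoy
row and ~0.5% carry three, exercising the 1R/3R rejection), and a
negative-binomial count table (dispersion 10) around log-normal planted
tissue profiles with ~15% silent family genes. The answer key records
family membership, every gene's ancestral lineage (= planted cluster
label), rank-adjacent same-lineage tandem arrays, per-branch ω, and
per-branch count bookkeeping satisfying the exact identity
final = ancestral × multipliers + gains − losses.

What passing tests show — and what they do not: recovery results
demonstrate the pipeline's correctness on data that satisfy its
assumptions (single-copy orthology within lineages, alignable sequences,
e-value ordering consistent with homology). They do not demonstrate
robustness to fragmented assemblies, missing annotations, domain model
drift, or cross-family sequence convergence.

## Problem sizes and determinism

Default study conditions (12 species, ~2,900 genes, ~120 family
members) run the full pipeline in a few seconds; bootstrap defaults to
1000 replicates in the pipeline configuration, with smaller counts used
in the test suite's sanity bands. All randomness flows from one numpy
`default_rng(seed)`; file emission orders are sorted, so a fixed seed
gives byte-identical output trees (hash-verified in the tests), and
every pipeline stage writes a manifest echoing its parameters and input
SHA-256 hashes.

## Known limitations

* NJ is O(n³) per tree; bootstrapping hundreds of taxa at 1000
  replicates is minutes, not seconds.
* CPM communities may overlap; the recovery ARI scores each gene by its
  largest community.
* The chain extractor's greedy best-first peeling is the conventional
  behaviour but is not globally optimal across blocks.
* The paper-scale quantities that depend on 35 real genomes (total
  family size, edge counts, per-category cluster counts) are inputs to
  arithmetic identities here, not reproduced measurements.
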