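# Methods

`ampatlas` implements a genome-wide survey of antimicrobial-peptide (AMP)
repertoires of the kind carried out for *Hydra*: species-restricted AMP
families born by recent tandem gene duplication, recognizable from peptide
structure alone, organized in dense chromosomal clusters, and in large part
transcriptionally silent yet primed for induction. This note documents the
models and heuristics behind each stage, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Peptide hallmarks and candidate classification

A precursor is summarized by length, net side-chain charge, a
bipartite-charge contrast, Trp fraction, a cysteine-spacing pattern, a
heuristic signal-peptide call, and dibasic processing sites.

**Charge scheme.** K, R = +1; D, E = −1; H = 0; termini ignored. This is
the standard AMP net-charge convention at neutral pH; no pKa titration is
attempted.

**Bipartite-charge contrast (`polarity_score`).** For a sequence of length
*L* the split point *s* ranges over the central half, *s* ∈ [⌈L/4⌉,
⌊3L/4⌋], and the score is the maximum of mean-charge(C-side) −
mean-charge(N-side). Ties break to the smallest split for determinism. A
charge-uniform sequence scores 0. Restricting *s* to the central half stops
one charged terminal residue from dominating.

**Signal peptide.** A rule-based reading of the classical tripartite
anatomy, replacing an external predictor: (1) a non-negative net charge in
the five-residue n-region; (2) a 7-residue window within residues 6–30
whose mean Kyte–Doolittle hydropathy reaches `h_min` = 1.5 (the h-region);
(3) a cleavage position in residues 15–45 whose −3 and −1 residues are
small ({A, G, S, C, T, V}, the von Heijne rule). The earliest qualifying
site is reported. `h_min` = 1.5 was set so that canonical hydrophobic-core
signal peptides pass while amphipathic mature regions do not. Sequences
shorter than 25 residues cannot carry a scorable signal and are returned
absent with a `too_short` flag.

**Cysteine grammar.** The six-Cys defensin scaffolds are encoded as allowed
ranges for the five inter-Cys gaps — alpha: 1 / 3–4 / 9 / 6–9 / 0; beta:
4–6 / 3–4 / 9–13 / 4–7 / 0; a beta match behind a ≥25-residue Cys-free
leader is a "big defensin". Six-Cys peptides failing every defensin
grammar but with Trp fraction ≥ `trp_min` = 0.08 (about four times the
background Trp frequency) are classified as Cys/Trp-rich (CWR-family)
peptides, the operational definition of that family. Absence of dibasic
sites is *not* required for the CWR call: the family is reported to lack a
conventional cleavage site, but making that a hard criterion would let a
single spurious KK reject a true member.

**Decision list.** Defensin grammar → `defensin_like`; CWR grammar →
`hycwr_like`; otherwise `amp_candidate` requires a called signal peptide,
a mature region ≤ `len_max` = 120 residues, and either a bipartite
contrast ≥ `pol_min` = 0.5 or a mature net charge ≥ `q_min` = +3. The
order matters: scaffold grammars are more specific than the generic
secreted-cationic test. All thresholds are configurable via
`FeatureConfig`.

## Moving-window membrane-activity scan

Each window (default 19 residues, about five helical turns; the window is
odd so a center residue exists) yields four descriptors: net charge, mean
Kyte–Doolittle hydropathy, the Eisenberg hydrophobic moment at 100°/residue
(|Σⱼ hⱼ·(cos jδ, sin jδ)|/n), and the hydropathy contrast between the
helical face aligned with the moment vector and the opposite face. The
σ-score is a standardized logistic regression over these descriptors,
trained on all windows of user-supplied positive and negative peptide sets
(windows inherit their peptide's label). Logistic regression was chosen
over a kernel machine because it keeps the probability semantics of σ, is
deterministic, and trains in milliseconds; the helix twist is fixed at 100°
with no secondary-structure prediction. Standardization statistics are
computed on the training split and stored in the model JSON, so a scan is
bit-reproducible from the model file alone. Peptides are ranked by mean σ
over windows with a default candidate threshold of 0.5 (the probability
midpoint).

Window-level labels are noisy — a true AMP precursor contributes its
signal-peptide and anionic-block windows as "positive" — so held-out
window accuracy saturates below 1 on realistic sets even when peptide-level
ranking is perfect. On the synthetic AMP/decoy sets (200 + 200 peptides)
held-out window ROC AUC is ≈ 0.92 and the peptide-level mean-σ margin
between planted AMPs and decoys is ≈ 0.4–0.5.

## Paralogue families and species-clade structure

**Alignment.** Global pairwise alignment (Biopython `PairwiseAligner`)
with BLOSUM62, gap open 10, gap extend 1 (first gap residue costs 10).
Identity is matches over aligned non-gap columns; coverage is aligned
non-gap columns over the shorter sequence length.

**Families.** Single linkage: an edge wherever identity ≥ `id_min` and
coverage ≥ `cov_min`; families are the connected components, named after
their lexicographically smallest member. Default `id_min` = 0.5,
`cov_min` = 0.6. The identity default was calibrated against the behavior
of global-alignment identity on unrelated sequences: with affine gaps the
aligner pairs similar residues opportunistically, so unrelated peptides
score identity up to ≈ 0.39 at coverage ≈ 0.93, and a 0.35 cutoff lets
single linkage chain everything into one component. At 0.5 the unrelated
tail is cleanly excluded while within- and cross-species family members
(identity > 0.7 at realistic divergence) stay connected. Raising `id_min`
can only refine the partition (monotonicity is tested).

**Trees.** Neighbor joining on p-distance (1 − identity). p-distance
rather than a model-corrected distance because AMP families are recent and
highly similar; saturation correction would add variance without signal.
The NJ implementation is canonical: Saitou–Nei Q criterion, ties broken
toward the lexicographically smallest representative-leaf pair, negative
branch lengths clamped to zero, final three nodes joined by the
three-point formulas. It is exact (topology and branch lengths to 1e-9)
on additive matrices. Families smaller than three get a star tree with a
flag. Bootstrap support is not computed.

**Clade statistics.** NJ trees are unrooted, so a "clade" is one side of
an edge bipartition; the whole leaf set also counts (a family entirely
from one species is that species' largest clade). For each species the
largest all-one-species side is reported. Founder lineages — family
members predating the within-species duplication burst — are leaves
belonging to no single-species clade of size ≥ `f_min` = 3.

## Genomic context

Coordinates are 1-based inclusive (GFF3) internally; BED peaks are
converted from 0-based half-open at the boundary. Gene models come from
`gene` features; CDS children are summed for coding length.

**Tandem clusters.** Per scaffold, family genes are sorted by start and
maximal runs with inter-gene gaps (next start − previous end) ≤ `max_gap`
and ≥ 2 members become clusters; singletons are reported unclustered.
Intervening non-family genes do not break a run — the loci are regions,
not strict adjacency — and strand is ignored (real AMP arrays are
strand-mixed). Two presets reflect two granularities of the same locus:
at `max_gap` = 50 kb a dense array resolves into sub-clusters (14 + 9 in
the reference scenario) which merge into one 23-member cluster at 200 kb.
Increasing `max_gap` never shrinks the largest cluster.

**TRG arrays.** A scan for candidate uncharacterized AMP families:
maximal runs of ≥ `min_run` = 10 consecutive genes, each with CDS ≤
`max_cds` = 1500 bp, whose mean pairwise peptide identity is ≥ `id_min` =
0.3. The identity filter is what separates duplication arrays from chance
runs of unrelated short genes (unrelated identity ≈ 0.15–0.25).

**Microsynteny loss calls.** For a family and a query/target species
pair: the locus is the query scaffold with the most family members; the
`k` = 5 non-family genes flanking it on each side are mapped through the
orthologue table; if ≥ `m_min` = 3 mapped anchors land on one target
scaffold, the anchored interval ± 50 kb margin is searched for any
target-species family member. `retained` if found, `lost` if the anchors
frame the window and no member lies inside, `unclassified` when anchors
are too few or discordant. A `lost` call therefore means the syntenic
locus is present but the gene is gone — the signature of a true family
loss rather than assembly absence.

## Omics integration

Counts live in an AnnData (cells × genes) with `cell_type` and optional
`body_region` labels. Normalization is the standard single-cell recipe
(scanpy: per-cell scaling to 10,000 counts, then log1p); raw counts are
kept in a layer because detection is defined on raw positives.

**Expression calls.** A gene is expressed in cell type *t* when its raw
count is positive in at least max(`min_cells` = 3, `detect_frac` = 0.01 ×
n_cells(*t*)) cells of *t*; globally expressed when any type qualifies.
These defaults are ordinary single-cell detection practice; raising either
threshold can only move genes from expressed to silent (tested
monotonicity). Specificity uses tau, τ = Σ(1 − x̂ᵢ)/(n − 1) over per-type
mean normalized expression: 0 for flat profiles, 1 for single-type
expression, bounded in between. Spatial restriction is true when ≥
`region_frac` = 0.8 of a gene's positive cells share one body region.

**Promoter priming.** The TSS is approximated by the gene-model 5′ end
(no UTR annotation is assumed). The upstream window is the 2,500 bp
immediately 5′ of the TSS, strand-aware, excluding the TSS base. A gene
is primed when any ATAC peak overlaps the window (half-open interval
arithmetic); the signed nearest-peak distance is negative upstream, zero
when a peak covers the TSS. Silent-but-primed genes are the intersection
of silent expression calls and positive priming calls — the set of
paralogues that look dormant but keep accessible regulatory regions.

## Synthetic data generator

The generator produces ground-truthed inputs with the statistical
structure the analysis assumes; it is the basis of every closed-loop test.

*Peptides.* Four templates: a bipartite AMP precursor (15-residue signal
peptide built to satisfy the detection heuristic, a short anionic block, a
dibasic site, and a long cationic block constructed as an idealized
amphipathic helix with an 8-Cys scaffold planted on non-basic positions);
a CWR-style peptide (six Cys at gaps 7/7/5/2/3 — outside both defensin
grammars — with Trp planted in each loop and a dibasic-free cationic
tail); a beta-defensin-spaced six-Cys peptide; and decoys drawn from a
background residue distribution slightly de-enriched in Cys and Trp and
weakly acidic on average, as real proteomes are.

*Evolution.* One founder per family evolves along a star species tree:
each species branch applies i.i.d. per-site substitutions with probability
`p_species` (default 0.08), then each tandem duplication copies a random
existing gene next to itself and lets both copies drift at `p_dup`
(default 0.02) per site. Substitutions preserve charge class (K↔R, D↔E,
neutral pool excluding Cys/Trp) and never touch protected positions
(cysteines, tryptophans, the signal peptide, planted dibasic sites), so
every copy keeps its planted structural label at any divergence, and
alignment identity stays analytically predictable. There are no indels.
Copy numbers are specified per species directly (the reference scenario
plants exactly 28), which keeps the planted layout exactly recoverable; a
stochastic copy number would make the headline counts replicate-dependent.

*Genomes.* Duplicates are placed adjacently with intra-cluster gaps
drawn uniformly from 2–20 kb; sub-clusters of one locus are separated by
120 kb (so they split at the 50 kb preset and merge at 200 kb); scattered
singletons are 300 kb apart. Family loci are flanked by five anchor genes
per side with one-to-one cross-species orthologue entries; a planted loss
removes the family gene in the target species but keeps its flanks. The
reference scenario mirrors the largest known Hydra AMP family: 28 copies
laid out 14 + 9 on one chromosome plus 5 scattered over three others, a
single-copy six-Cys family lost in the second species, a 30-gene array of
short near-identical taxon-restricted genes, and 40 background decoys.

*Omics.* Counts are negative binomial (dispersion 0.5, the standard
single-cell overdispersion model; mean 5 per expressed gene in its cell
type), over 8 cell types × 40 cells. 24 of the 28 main-family paralogues
are silent (all-zero); of the 4 expressed, one is confined to a
tentacle-restricted neuronal population (the planted region-restricted
gene) and the rest to the germline. Twelve housekeeping genes keep every
cell's total positive. Every family gene receives a 400 bp ATAC peak
centred 1,250 bp upstream of its TSS, strand-aware; decoys are peak-free.

*What it does not emulate.* Indels and alignment ambiguity; rate
heterogeneity and homoplasy beyond the small charge-class pools;
pseudogenization; doublets, ambient RNA, and batch effects in the counts;
peak-width and signal-strength variation in the ATAC track; realistic
nucleotide sequence (the genome FASTA is an N-run stub, since no stage
reads nucleotides). Passing closed-loop tests therefore demonstrates the
correctness of the bookkeeping and the statistics under the model's
assumptions, not robustness to the full noise structure of real data.

## Replicate ensembles and problem sizes

The species-monophyly property is evaluated on two-species histories with
six copies per species (five duplications, ≥ 3 as required), within-species
drift `p_dup` = 0.03 ≤ 0.05 per site, and a deep species split
(`p_species` = 0.15). The split depth reflects the biology being modeled —
the real species diverged on the order of 100 Myr before the recent
duplication bursts — and is what makes strict monophyly the expected
outcome: if the species branch is made as short as the within-species
drift, deep paralogue lineages genuinely straddle the species boundary and
no correct method would recover monophyly at high frequency. Loss-call
ensembles use 50 full scenario replicates in the test suite (10 in the
acceptance script, which also recomputes every other quantity); monophyly
uses 50 (25 in the script). These sizes keep the default suite and script
in the tens of seconds while leaving binomial noise far from the asserted
margins.

## Numerical and degenerate-input choices

Polarity ties break to the smallest split; NJ ties to the smallest leaf
pair; cluster ids are scaffold:start; family ids are the smallest member
id — all outputs are byte-reproducible for a fixed seed. Peptides shorter
than the window produce an empty σ profile with NaN mean rather than an
error. Zero-total cells are dropped with a warning; an all-zero matrix is
an error. Genes on scaffolds absent from the peak set get `primed=false`
with NaN distance. Empty GFF3 input yields an empty gene list.

## Known limitations

Signal-peptide and cleavage-site detection are deliberately simple
rule systems and will disagree with learned predictors near their decision
boundaries. Identity-based single linkage cannot split families connected
by a chain of intermediate paralogues. p-distance NJ underestimates deep
divergence. The TRG-array scan reports any dense run of short similar
genes, including known AMP clusters — it is a candidate generator, not a
classifier. Tau is computed on per-type means and is sensitive to cell
type granularity. The TSS approximation by gene-model 5′ end shifts
upstream windows on genes with long 5′ UTRs.
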