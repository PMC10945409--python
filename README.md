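# ampatlas

Genome-wide mining and characterization of antimicrobial-peptide (AMP)
repertoires, built around the situation found in *Hydra* and similar
systems: AMPs encoded by fast-evolving, taxonomically restricted gene
families that expand by tandem duplication, sit in dense chromosomal
clusters, and are in large part transcriptionally silent yet carry open
promoters. The package is aimed at comparative genomicists and
immunologists who have protein predictions, a genome annotation, a
single-cell expression atlas, and an ATAC peak set, and want to go from
those inputs to a characterized AMP repertoire without wet-lab screening.

## What it computes

1. **Peptide hallmarks** (`ampatlas.peptides`) — net charge *q* under the
   standard scheme (K,R = +1; D,E = −1), the bipartite-charge contrast
   max₍ₛ₎ [mean q(s+1..L) − mean q(1..s)], Trp fraction, cysteine-spacing
   grammars for the six-Cys defensin scaffolds, a rule-based
   signal-peptide call (n/h/c-region + von Heijne (−3,−1) rule), and
   dibasic processing sites; a decision list labels each precursor
   `amp_candidate`, `defensin_like`, `hycwr_like`
   (cysteine/tryptophan-rich), or `none`.
2. **Membrane-activity scan** (`ampatlas.scan`) — per-window σ-scores
   (probability of membrane activity) from a standardized logistic model
   over net charge, mean Kyte–Doolittle hydropathy, the Eisenberg
   hydrophobic moment μH = |Σⱼ hⱼ·(cos jδ, sin jδ)|/n at δ = 100°, and
   helical-face amphipathic contrast; peptides ranked by mean σ.
3. **Paralogue families** (`ampatlas.families`) — single-linkage families
   over global-alignment identity (BLOSUM62, gap 10/1), neighbor-joining
   trees on p-distance, largest species-specific clades, and founder
   lineages (members outside every large species clade).
4. **Genomic context** (`ampatlas.genome`) — maximal tandem-cluster runs
   under a bp-gap threshold (with 50 kb / 200 kb presets for two
   granularities of the same locus), arrays of short similar
   taxon-restricted genes, and microsynteny-based family-loss calls from
   flanking-gene anchors mapped through an orthologue table.
5. **Omics integration** (`ampatlas.omics`) — expressed/silent status per
   gene from a cell-annotated count matrix, tau expression specificity,
   body-region restriction, ATAC promoter priming within 2.5 kb upstream
   of the TSS (strand-aware), and the silent-but-primed gene set.
6. **Synthetic data** (`ampatlas.simulate`) — a ground-truthed generator
   for all of the above (duplication histories, genome layouts, count
   matrices, peak tracks), used by the test suite as a closed loop.

See `docs/methods.md` for the models, defaults, and limitations.

## Worked example

Run the built-in two-species scenario end to end:

```sh
ampatlas report --seed 1 --out out/
```

Selected fields of the printed JSON report (full report in
`out/report.json`):

```json
{
 "families": {
  "periculin_like": {"by_species": {"speciesA": 28, "speciesB": 8}, "total": 36}
 },
 "clusters": {
  "periculin_like": {
   "preset_50k":  {"clusters": {"chr10": [14, 9], "chrB10": [8]}, "n_unclustered": 5},
   "preset_200k": {"clusters": {"chr10": [23],    "chrB10": [8]}, "n_unclustered": 5}
  }
 },
 "expression": {
  "n_genes": 28, "n_silent": 24, "n_expressed": 4,
  "n_primed": 28, "n_silent_but_primed": 24
 },
 "synteny": [
  {"family": "hydramacin_like", "status": "lost",     "target": "speciesB"},
  {"family": "periculin_like",  "status": "retained", "target": "speciesB"}
 ]
}
```

Reading: the main AMP family has 28 members in species A; at the 50 kb
cluster preset they resolve into chromosome-10 clusters of 14 and 9 plus 5
scattered copies, which merge into one 23-member dense cluster at 200 kb.
Of the 28 paralogues, 24 have no detectable expression in the cell atlas
but all 28 carry an ATAC peak in their upstream window, so the 24 silent
genes are all silent-but-primed. The single-copy six-Cys family is called
`lost` in species B by microsynteny (its flanking anchors are present, the
gene is not), while the main family is `retained`.

Individual stages run on your own files:

```sh
ampatlas simulate --seed 1 --out data/           # or bring your own inputs
ampatlas features data/proteins.faa --out features.tsv
ampatlas families data/proteins.faa --out families.tsv --trees-out trees/
ampatlas clusters --gff data/genes_speciesA.gff3 --families families.tsv --max-gap 50000
ampatlas expression --matrix data/expression.mtx --metadata data/cell_metadata.tsv \
    --genes data/expression_genes.tsv --cells data/expression_cells.tsv \
    --gff data/genes_speciesA.gff3 --peaks data/peaks.bed
```

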