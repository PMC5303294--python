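# homoeoflow

Homoeologue-resolved expression analysis for nascent allopolyploids.

When a tetraploid (AABB) and a diploid (DD) plant are crossed, the
allotriploid hybrid (F1, ABD) and its genome-doubled allohexaploid (S1,
AABBDD) carry up to three copies — homoeologues — of every ancestral gene.
Hybridization and whole genome doubling (WGD) each reshape how those copies
are transcribed: homoeologues can be suppressed in the hybrid and restored
after doubling, group totals can deviate from the mid-parent value (MPV),
and a group's total can track one parent (expression level dominance, ELD).
`homoeoflow` is a reusable pipeline for quantifying and classifying these
behaviours from RNA-Seq, built for the small replicate numbers (n = 2 per
genotype) such crossing designs usually afford, and shipping a seeded
synthetic-experiment generator so every stage can be validated by
parameter recovery.

## What it computes

* **Homoeologue grouping** — all-vs-all protein comparison between
  subgenomes (local DP alignment, BLOSUM62, shared-k-mer seeding, E ≤ 1e−5,
  identity ≥ 90%, coverage ≥ 90% of the shorter sequence) resolved into
  triplets, duplets and singletons; within-genome duplicates resolved by
  best summed score.
* **Subgenome read assignment** — reads placed on member transcripts and
  voted to a subgenome by the bases they carry at diagnostic alignment
  columns; an artefact filter drops genes expressed in the parent that
  structurally lacks their subgenome.
* **Quantification** — FPKM = count / ((length/10³)·(total/10⁶)) from
  assigned counts; genes retained when FPKM > 1 in at least one sample of
  the lineage; DESeq-style median-of-ratios size factors.
* **Differential transcription** — an exact conditional negative-binomial
  test on the two groups' count sums, with method-of-moments gene-wise
  dispersions, a local-regression mean–dispersion trend, the conservative
  `max(gene-wise, trend)` rule, and Benjamini–Hochberg FDR at α = 0.05.
  For a gene with group sums $K_A, K_B$ and size-factor sums $s_A, s_B$,
  the common concentration is $\hat q = (K_A+K_B)/(s_A+s_B)$, each group
  sum is NB with mean $\hat q s_g$ and moment-matched dispersion, and the
  two-sided p-value adds the probabilities of all splits of $K_A+K_B$ no
  more probable than the observed one.
* **Classification** — per homoeologue pair and genotype, unequally
  transcribed homoeologues (UTH) on length-corrected counts; additivity
  against an MPV pseudo-sample; ELD with direction (progeny similar to one
  parent, different from the other, parents differing); restoration of
  F1-disturbed genes after WGD with boxplot statistics (1.5·IQR whiskers);
  expressed-singleton Venn partitions and single-parent transcription.
* **Reporting** — log2(FPKM+1) Pearson correlations, a complete-linkage
  dendrogram in Newick, generic hypergeometric term enrichment, and
  figure-style summary tables with self-consistent percentages.

## Worked example

Simulate a desk-scale experiment (100 triplets, 60 duplets, 150 singletons,
two replicates per genotype, default planted effect fractions) and run
the whole analysis:

```
$ homoeoflow run-all --seed 11 --outdir out
analysed 141 groups; outputs in out
```

`out/summary/uth.tsv` (excerpt):

```
setting pair  n_tested  left_gt  left_lt  pct_uth
F1      A:D        100       24        0     24.0
S1      A:D        100       16        1     17.0
parents A:D        100        8        5     13.0
```

24% of triplets have A > D transcription in the allotriploid — the planted
D-homoeologue suppression — and the fraction falls to 17% after genome
doubling as a planted subset of suppressions reverts. `de_F1_vs_parent`
shows the same asymmetry per homoeologue (24.2% of D copies down versus
5.2% / 1.9% for A / B), `restoration.tsv` reports 26 of 54 disturbed D
homoeologues restored by WGD, and the ELD table counts 16 ELD-ab versus 2
ELD-d groups in F1 (the planted ~5:1 asymmetry). The dendrogram
(`out/dendrogram.nwk`) places the two F1 and two S1 libraries as sister
clades before either joins the AABB parent, with the DD parent as the
outlier (topology of the emitted Newick, branch lengths elided):

```
((P_D_1,P_D_2),((P_AB_1,P_AB_2),((S1_1,S1_2),(F1_1,F1_2))));
```

Real data enter the same way through TSV tables: a genome-resolved
gene × sample count matrix, a sample sheet (`sample, genotype ∈ {P_AB,
P_D, F1, S1}, replicate`), a `groups.tsv` from `homoeoflow group`, and gene
lengths (`homoeoflow classify --counts ... --samples ... --groups ...
--lengths ...`).

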