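# Methods

## The design being modelled

The pipeline targets a two-step allopolyploidization design: a tetraploid
parent P_AB (AABB), a diploid parent P_D (DD), their allotriploid hybrid F1
(ABD) and the spontaneously genome-doubled allohexaploid S1 (AABBDD), each
profiled by bulk RNA-Seq with two biological replicates per genotype.
Genes are organised in homoeologue groups — triplets (one copy per
subgenome), duplets (AB / AD / BD) and singletons — and every analysis is
phrased at either the per-copy level (homoeologue versus its own parent,
homoeologue versus sibling homoeologue) or the group-total level (progeny
total versus parents or mid-parent value).

## Synthetic experiment generator

The generator (`homoeoflow.simulate`) emulates that design so each
downstream stage can be validated by parameter recovery.

**Counts.** Each group draws one baseline per-copy mean, log-uniform on
`baseline_mean_range` (default 50–500 on the count scale), shared by all
members — mirroring the near-unity median homoeologue abundance ratio seen
in real allopolyploid leaf transcriptomes. Counts are negative binomial
with `variance = mu + alpha * mu**2`, `alpha = nb_dispersion` (default
0.05, a typical bulk biological-replicate value); per-sample size factors
are uniform on [0.7, 1.3], enough to exercise normalisation without
overwhelming it. Parents have structural zeros for the subgenome they
lack. The generator works on the absolute per-copy convention — a gene's
expected count is `baseline * 2^(planted log2fc) * size factor` — and the
transcriptome-relative character of real RNA-Seq is handled in the
analysis layer by per-contrast normalisation (below).

**Planted effect classes** (mutually exclusive per group; fractions are
configuration, defaults follow the magnitudes a synthetic-wheat experiment
reports):

| class | default fraction | mechanism |
|---|---|---|
| `f1_down_restored` / `f1_down_maintained` | 0.326 of D-carrying groups, split 0.38 / 0.62 | D copy at `2^-2` of baseline in F1; restored genes return to baseline in S1 |
| `eld_ab` | 0.10 | DD parent's copy shifted `±1.5` log2 off the shared mean; progeny stays at the genome-wide norm (so the D homoeologue is re-regulated relative to its parent) |
| `eld_d` | 0.02 | every progeny copy moves with the deviant DD parent |
| `nonadd_up` / `nonadd_down` | 0.004 / 0.032 | all F1 copies scaled `2^±1.5`; reverts in S1 |
| `singleton_expressed` / `singleton_silent` | 0.3 / 0.7 of singletons | silent singletons have zero mean everywhere |

ELD is planted relative to the genome-wide norm rather than as equality of
raw totals because that is the quantity a size-factor-normalised test
measures: on a mostly unchanged transcriptome, "progeny similar to parent
X" operationally means "the progeny/parent-X ratio sits at the norm".  A
consequence worth stating: planted ELD groups also genuinely deviate from
the MPV (a progeny matching one of two differing parents cannot be
mid-parent), by −1.94/−0.44 log2 for `eld_ab` and +0.81/−1.15 for `eld_d`
depending on the sign of the parental shift. ELD and non-additivity are
overlapping, not exclusive, descriptions of the same groups — as in real
data.

**Sequences.** One ancestral in-frame transcript per group (uniform sense
codons); members mutate each site independently at
`divergence_rate × codon-position weight`, weights (0.25, 0.15, 2.6) with
mean 1. The third-position concentration emulates purifying selection:
at the default 2% nucleotide divergence, protein identity stays ≈ 95%, as
for real homoeologues, where a uniform model would push amino-acid
divergence to ≈ 8% and break 90%-identity grouping. Mutations creating a
stop codon are repaired at the third position. The expected pairwise
nucleotide identity has the closed form
`mean_w[(1 − d·w)² + (d·w)²/3]` and is asserted in tests.

**Reads.** Unpaired, fixed length (default 100 bp), uniform start on the
gene's own transcript, independent substitution errors (default 0.2%),
constant quality; read names carry `gene|genome|group` audit tags. Pairing
is omitted because it adds no logic to diagnostic-site assignment.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: introns/splicing and isoforms, within-genome
allelic variation, positionally biased coverage, quality-score structure,
correlated dispersion across genes, partial (quantitative) ELD, and
mapping artefacts beyond the wrong-parent class the artefact filter
targets.

## Grouping

All-vs-all protein comparison between (never within) subgenomes: local
dynamic-programming alignment (BLOSUM62, gap open −11 / extend −1) behind
a shared-5-mer prefilter standing in for BLAST seeding. The E-value proxy
`E = K·m·n·exp(−λS)` uses fixed gapped-BLOSUM62 constants (λ = 0.267,
K = 0.041) and acts purely as a filter alongside identity ≥ 0.90 (matches
over alignment columns) and coverage ≥ 0.90 of the shorter sequence — the
span denominator is a package choice. Connected components with one gene
per subgenome become groups; in components with within-genome duplicates,
subgenomes with a unique candidate are fixed first and each remaining
subgenome keeps the candidate with the highest summed edge weight to the
kept members (ties: lexicographic id), displaced genes becoming
singletons. On instances where within-group similarity dominates (the
regime the thresholds enforce), this greedy rule attains the exhaustive
optimum of total within-group score; the acceptance suite checks that on
small instances.

## Read assignment

For each multi-member group, member transcripts are aligned (column-wise
when equal length, star alignment to the first member otherwise) and
columns where members disagree become diagnostic sites. A read is placed
on candidate members (exact substring, then edlib infix alignment within
`max(2, len/20)` edits, candidates seeded through a 21-mer index); members
tied at the best edit distance are candidate placements. Bases at covered
diagnostic sites each support the set of subgenomes carrying that base;
the intersection decides: a single survivor labels the read, disagreement
or a multi-genome survivor set leaves it ambiguous, no placement leaves it
unassigned. A uniquely placed read with no diagnostic coverage is also
ambiguous (conservative; with substitution-only divergence such reads only
arise under sequencing error). Labels partition the read set; with
error-free reads a subgenome label is provably correct, which the
acceptance suite asserts as 100% audit-tag agreement.

The artefact filter mirrors the wrong-parent discarding rule: any gene
whose subgenome is absent from a parent yet shows FPKM > 1 in a replicate
of that parent is excluded from all downstream contrasts. The threshold
reuses the pipeline-wide retention constant; at desk-scale depths a single
stray read can exceed it, which only makes the filter conservative.

## Quantification and normalisation

FPKM uses the sum of assigned counts per sample as its denominator (the
natural choice when only assigned counts exist downstream). Retention:
FPKM > 1 (strict) in ≥ 1 sample of the lineage, the lineage being the
four genotypes of one cross. Homoeologue-vs-homoeologue comparisons first
rescale counts to the pair's geometric-mean length.

Cross-sample normalisation is DESeq's median-of-ratios, with two
deliberate refinements:

* **Within-library homoeologue pairs share the library's depth factor.**
  Homoeologues measured in the same library need no cross-column
  normalisation; estimating one from the data lets a planted asymmetric
  cluster (e.g. 26% of pairs with A≫D) shift the median by ~0.15 log2 and
  manufacture opposite-direction calls. Cross-genotype pairs (the
  parents setting of the UTH table) still use median-of-ratios.
* **Group-total contrasts are stratified by member composition** (triplet,
  AD duplet, BD duplet; AB duplets have no DD-parent copy and are excluded
  from MPV/ELD). A no-change group's progeny/parent total ratio is a
  composition-dependent dosage constant (3:2 for triplets versus 2:1 for
  AD duplets against P_AB), which in-stratum normalisation absorbs and a
  pooled normalisation cannot. P-values are pooled across strata before a
  single BH pass per contrast. Parental totals are used as measured, with
  no ploidy rescaling.

## The exact NB test

Per-gene dispersions are method-of-moments on normalised counts,
`(pooled within-condition variance − ξ·mean)/mean²` with ξ the mean
inverse size factor; a non-robust lowess (it = 0, frac 0.4) of the raw
estimates over log10 mean provides the trend — the raw estimates are
roughly unbiased but heavily right-skewed at 1–2 degrees of freedom, so a
local mean preserves the level where a robust fit would trim it down. The
working dispersion is `max(gene-wise, trend)`, floored at 1e-8; this
conservative sharing rule costs sensitivity at low means (≈ 15% at mean
50, dispersion 0.05, n = 2) and is the main power limiter of the whole
pipeline. Designs with no replicated condition raise an error directing
the caller to supply dispersions externally (trend-only mode).

The test conditions on the two groups' count sums: with the common
concentration estimated from the pooled normalised counts, each group sum
is NB with moment-matched dispersion `alpha · Σs_j²/(Σs_j)²`, and the
two-sided p-value sums the probabilities of all splits whose probability
does not exceed the observed split's (ties included). The 0.5 pseudo-count
appears only in the reported fold change. BH adjustment is the standard
step-up with monotonicity enforcement; calls are up/down/ns at q < 0.05,
with a significant zero-fold-change anomaly logged and reported ns.

## Classification rules

* **UTH**: per pair (A:B, A:D, B:D) and setting (parents, F1, S1), the
  exact test on length-corrected member counts of triplet groups passing
  parental retention (any member with parental FPKM > 1); BH per setting ×
  pair.
* **Additivity**: MPV pseudo-replicates are rounded means of normalised,
  sorted-order-paired parental totals; progeny versus MPV with dispersions
  estimated from the pseudo-matrix itself (the averaging's variance
  reduction is then reflected in the estimates); q < 0.05 splits
  nonadd_up / nonadd_down from additive.
* **ELD**: defined only where the parents differ significantly. Progeny
  indistinguishable from one parent and different from the other gives
  ELD-ab / ELD-d; significant same-direction departures from both parents
  are transgressive; direction is higher_parent when the matched parent
  carries the larger normalised total.
* **Restoration**: genes with a non-ns F1-vs-own-parent call are restored
  if the S1-vs-parent call is ns, else maintained (the rare
  opposite-direction significant S1 call is folded into maintained).
  Boxplot statistics use quartiles with whiskers at the most extreme point
  within 1.5 IQR.
* **Singletons**: expressed = FPKM > 1 in ≥ 1 sample of a genotype;
  single-parent transcription = expressed in exactly one parent and at
  least one progeny generation.

## Validation experiment sizes

Chosen as the package's desk-scale validation conditions:

* Null calibration and power: 5,000 genes, n = 2 vs 2, dispersion 0.05;
  null means 50–500, planted-effect means 100–1000 with 10% 4-fold
  changes. Observed: raw p < 0.05 rate ≈ 0.034–0.041 (the shortfall from
  0.05 is the max-rule's conservatism), BH calls ≈ 0 on the null,
  sensitivity ≈ 0.92 at FDR ≈ 0.03.
* Classification recovery: 5,000 groups (2,000 triplets, 1,500 duplets,
  1,500 singletons), baseline means 100–1000 — the detection regime the
  power experiment establishes for n = 2; at the generator-default 50–500
  range the max-rule's low-mean power loss, not the classifiers, caps
  per-category recovery. UTH and ELD recover planted fractions within
  0.03 on the default effect mix; additivity is validated on a
  configuration where mid-parent deviations are the only planted class,
  because planted ELD necessarily contributes real MPV deviations of its
  own (see above) — isolating a signal to validate its classifier is the
  standard recovery design.
* Read assignment: ≈ 40,000 error-free reads over 50 groups; grouping:
  120 homoeologue pairs at 2% divergence; dendrogram property: 20 seeded
  default-size experiments.

## Known limitations

Single-replicate designs are not tested end-to-end (trend-only dispersion
entry exists but no bundled single-replicate contrast); the E-value proxy
is uncalibrated by design; the star MSA records diagnostic sites only at
reference-aligned columns, so member-specific insertions are invisible to
voting; group-total tests assume the stratified-norm model and would need
re-derivation for designs whose neutral dosage ratios vary within a
stratum; enrichment takes a user-supplied gene→term map and does no
ontology propagation.
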