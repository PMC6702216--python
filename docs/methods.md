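# Methods

This note documents the statistical procedures `itrpred` implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Coordinates and classification

All internal coordinates are 0-based half-open; GFF3 input/output converts
from 1-based inclusive at the boundary. Merging and classification are
strand-agnostic: assembled transcript fragments are pooled across RNA-seq
datasets, and any two fragments sharing at least one base are merged
(bookended half-open intervals share no base and stay separate). Each
merged region is classified by priority — one shared base with an exon
makes it an exon region regardless of other overlap, then intron, then
pseudogene, else intergenic (an ITR). Fragments are merged *before*
classification, so a region's class reflects its full merged extent.

Runs of ≥ 40 ambiguous nucleotides (the typical read length, hence
unalignable) are treated as likely-unmappable and excluded from all space
denominators. Random intergenic controls are drawn by rejection sampling
with uniform starts (10,000 retries per requested length), then filtered
post hoc for any ambiguous base — so a few percent of requested lengths
may be dropped, as with real assemblies. Distances between regions count
the bases strictly between the closest interval ends; overlap is distance
zero.

## Coding-like and repetitive flags

A region is coding-like when it carries a protein domain in any translated
frame or a translated protein match with E-value < 10⁻⁵. Repetitive
flagging has two routes: (1) carrying a protein domain enriched among
benchmark interspersed repeats relative to exon transcribed regions —
one-sided Fisher's exact test (the enrichment direction is the hypothesis;
the two-sided variant would also reject depletion, which is not evidence
of repetitiveness), Benjamini–Hochberg adjusted across every domain
observed in either group, adjusted p < 0.05; or (2) a within-species
duplicate count at or above a threshold chosen by maximizing F₁ (the
unweighted harmonic mean; "F-measure" without a subscript is read as F₁)
of the rule "repetitive iff count ≥ t" over all observed counts plus
max+1, ties toward the smallest threshold. The ≥ convention means a
sequence exactly at the threshold is repetitive.

## Empirical-null conservation calling

Best cross-species hits are compared against the best hits of random,
*unexpressed* intergenic sequences — the natural null for asking whether a
transcribed region is more conserved than expected for neutral intergenic
DNA. The percentile is computed on the significance scale
s = −log₁₀ E (E = 0 capped at s = 180, matching the feature cap) with
hitless sequences contributing s = 0; this handles hitless nulls
coherently, which a percentile on raw E-values cannot. The threshold is
the ascending nearest-rank 95th percentile; a query is conserved only if
its hit is *strictly* more significant. When most nulls are hitless the
threshold collapses to the search reporting cutoff (as in compact
genomes); repeat-rich genomes push it far lower. Because 5% of sequences
drawn from the null process exceed the threshold by construction, 5
percentage points are subtracted from final conserved proportions
(floored at zero).

Substitution rates between a sequence and its best within-species match
use a global alignment (EDNAFULL scoring, affine gaps open 10 / extend
0.5) and the Jukes–Cantor correction K = −¾ ln(1 − 4p/3) on the mismatch
fraction p over aligned columns. A pairwise GTR fit is over-parameterized
for two sequences, so JC is used and the raw p-distance is reported
alongside K; users with externally computed rates can attach them to match
records directly. The correction is undefined at p ≥ 0.75 (saturation)
and raises.

## Expression conservation

Expression arrives as per-dataset FPKM plus a presence flag (when only an
FPKM matrix is available, presence defaults to FPKM > 0). A tissue's
level is the mean FPKM over its replicate datasets with presence evidence
(the single value when only one replicate is expressed, 0 when none).
Expression breadth counts collapsed tissues — the two seed stages collapse
to one tissue, as do the two inflorescence stages — with presence in at
least one constituent dataset.

Percent commonality between two expressed regions is
|A ∩ B| / |A ∪ B| × 100 over the five tissues shared across species
(embryo, endosperm, seed, leaf, anther). The union denominator is chosen
because "total expressed tissues" is otherwise ambiguous for a pair; the
union makes the statistic symmetric and bounded with 100% exactly at
identical tissue sets. Because expected commonality depends strongly on
breadth, exon controls are matched on the unordered breadth pair of each
query pair (two sampled per query, without replacement; queries without a
matching control are skipped with a warning), and the random expectation
draws 25 tissue-set pairs of matching breadths with tissue probabilities
proportional to tissue frequency among expression-conserved regions.

Neighbor expression-correlation profiles pair adjacent regions along each
chromosome, categorize them (within-gene; gene/gene tandem, head-to-head,
tail-to-tail by annotated strands; gene/ITR and gene/pseudogene by
up/downstream position relative to the gene's orientation — ITRs are
unstranded; ITR/ITR), bin them by gap distance, and report the median
Pearson correlation of tissue-level expression per bin, excluding pairs
with a zero-variance vector. A random baseline draws up to 10,000
same-category pairs from the whole region set.

## Synteny and duplicate retention

Syntenic blocks are consumed as ordered anchor-pair tables with per-anchor
Ks (collinearity detection and Ks computation are upstream). A block's
median anchor Ks dates it: ≥ 0.7 assigns the ancient rho/sigma WGDs shared
by the grasses; maize blocks below 0.7 assign the ~12 MYA maize WGD;
non-maize blocks below 0.7 have no WGD of known age and are labeled
`none`, excluded from WGD summaries (generalizing the exclusion of the one
recent rice block observed in real data). Genic regions find their
syntenic partner through the anchor gene containing them (best hit
overlapping the partner gene); intergenic regions through the genome-B
interval circumscribed by the partners of the flanking anchor pair (hits
must lie strictly inside, never on an anchor itself). A region spanning an
anchor boundary is assigned to the inter-anchor interval holding the
majority of its bases, ties toward the upstream interval. Retention
summaries report, per class and WGD label, the fraction of regions with a
syntenic duplicate, and, among duplicates, the fraction whose partner
locus is overlapped by a transcribed region, in three equal-width K bins
over [0, 0.08] by default (where retained duplicates concentrate).

## The 44 features

Four families, fixed registry order (the registry is canonical within
this package):

| family | n | features |
|---|---|---|
| transcription | 12 | level per tissue (9), max over datasets, median over expressed datasets, breadth |
| conservation | 3 | −log₁₀ best cross-species E (no hit → 0, E = 0 → 180), proportion overlapping a conserved nucleotide block, median per-base phastCons over that overlap (0 without overlap) |
| chromatin | 13 | fractional peak coverage per histone mark (10 marks, 8 activation + 2 repression by default, config-driven), counts of overlapping activation/repression marks, mean MNase depth |
| methylation | 16 | CG/CHG/CHH level in 4 tissues (12), gene-body-methylation flag per tissue (4) |

Methylation levels require ≥ 5 reads over ≥ 5 cytosine sites, else the
cell is missing. The GBM flag tests each context against the genome
background with a one-sided binomial test, BH-adjusted across all regions
within one context × tissue family (the family scope is a design choice;
the per-context family matches how one background is shared), FDR ≤ 0.05;
flag 1 means CG significantly enriched while CHG and CHH are not, and the
flag is missing whenever the CG level itself is missing. The median of
expressed datasets is 0 when a region is expressed nowhere (keeping the
feature numeric for the forests). Missing methylation cells propagate as
NaN into imputation.

## Prediction

Missing features are imputed by chained single-equation regression:
initialize with column medians (modes for binary flags), then for 10
cycles revisit features in ascending missingness, re-predicting missing
cells from all other features by linear regression (logistic for binary
flags, on standardized predictors). Single imputation with a fixed seed is
deliberate — the downstream ensemble supplies the variance estimate the
analysis needs.

Balanced datasets hold min-class-size members of each class, sampled
without replacement within a set (equal-sized classes make every set the
full benchmark, with variation coming from CV shuffling and forest
randomness). Each two-class forest uses 500 trees, depth 10, 25% of
features per split — the best cell of the depth × feature-proportion sweep
exposed by `parameter_sweep`. Benchmark members are scored out-of-fold
under stratified 10-fold CV; all other regions are scored by a forest
refit on the full balanced set, maximizing training data for the applied
model. Scores are tree-vote fractions, so they live on the 1/500 grid;
the functional likelihood is the median over balanced sets (even counts
average the central pair).

T₁ is the ascending nearest-rank 95th percentile of nonfunctional-class
likelihoods; T₂ the 5th percentile of functional-class likelihoods; calls
use strict inequalities and exact threshold equality stays ambiguous.
Thresholds are calibrated on the out-of-fold likelihoods of benchmark
members. On very separable data the thresholds can cross (T₂ > T₁); a
warning is emitted and the ambiguous zone is empty.

The three-class model (phenotype exon / transcribed pseudogene /
transcribed miRNA) uses 20-fold CV with 250 balanced sets per fold by
default, compensating for the scarcity of miRNA benchmarks; scores are
mean per-class vote fractions (summing to 1), the call is the argmax with
exact ties broken toward pseudogene (the conservative nonfunctional
call), and exon- or miRNA-called regions are "functional".

AUC-ROC is computed by the Mann–Whitney rank statistic with midranks for
ties. The algorithm comparison draws 100 bootstrap repeats of disjoint
balanced train/test splits (225/25 per class), quantile normalizes
against a rank-average reference learned on the training split only, and
compares the full forest, logistic regression, and forests on
LASSO-selected features per penalty; a penalty selecting zero features
degrades that arm to an intercept-only model (AUC 0.5) with a warning.

## The synthetic-data generator

The generator emulates every pipeline input with planted truth: an
annotated two-chromosome ~1.2 Mbp genome (300 genes with exon/intron
structure, ~60 pseudogenes, N runs recovered as unmappable space);
per-dataset transcript fragments and FPKM/presence matrices under the
11-dataset / 9-tissue layout with exon-derived regions longer, higher and
broader than ITRs; best-hit E-value tables where null sequences draw from
a hitless-inflated exponential significance tail and a per-class planted
fraction receives hits far above the null 95th percentile; within-species
duplicates with a recent/ancient K mixture (log-normal around 0.02 and
0.7); a syntenic block with planted intergenic duplicates at an exact
retention fraction; class-dependent histone peaks; bisulfite counts with
a designated gene-body-methylated subset (CG ~0.6 versus background 0.25,
CHG/CHH at background; 90% of cells above the coverage minimums); and a
44-feature benchmark table with class-conditional family shifts.

Benchmark effect sizes were fixed once to reproduce the difficulty
observed in real data — individual features discriminate weakly (median
single-feature AUC ≈ 0.66 here) while the combined ensemble discriminates
well (AUC ≈ 0.99) — because both the 5%-rate threshold calibration and
the ensemble's value-over-naive-classifiers story are only meaningful
when the classes genuinely overlap. Directions follow the biology:
exon-like regions score high on expression, conservation, activation
chromatin and gene-body methylation; pseudogene-like regions low, with
higher non-CG methylation; miRNAs sit between on expression and low on
protein-level conservation while retaining conserved-block overlap.
Setting every family effect to zero makes the classes indistinguishable
and drives the ensemble to AUC ≈ 0.5.

All draws flow from one scenario seed through per-stage generators, so
any stage can re-run independently and byte-identically.

What the generator does **not** emulate: read-level sequencing noise and
mapping artifacts, sequence homology (match tables are drawn, not
aligned), linked features (families are sampled independently given the
class, whereas real expression, chromatin and methylation covary),
genome-scale repeat structure, and annotation error. Passing tests
therefore demonstrate that the statistics are implemented correctly and
calibrated as specified — not that the biological conclusions transfer to
any particular genome.

## Problem sizes and runtime choices

The default test-scale conditions are 300 regions per benchmark class,
25 balanced sets with 10-fold CV for two-class ensembles, 1,000 null plus
1,000 query sequences for conservation calibration, 300 regions for
methylation recovery, and a reduced three-class ensemble (5 folds × 25
sets × 100 trees, 60 miRNAs). These sizes keep each end-to-end check in
the minutes range on a single CPU while leaving the operations' defaults
at their full values (100 sets; 20 × 250 × 500 for three-class).

## Known limitations

- The K estimate is Jukes–Cantor, not GTR; highly diverged pairs are
  better served by attaching externally computed rates to match records.
- Intergenic syntenic matching requires hits strictly inside the
  circumscribed interval; partner loci that drifted across an anchor
  boundary are missed by design.
- `neighbor_expression_correlation` pairs only adjacent regions; run-on
  patterns spanning several intervening regions are not chained.
- The GBM binomial test treats reads as independent Bernoulli trials;
  clustered reads over few cytosines can overstate significance (the
  5-read/5-site minimum is the guard).
- Thresholds T₁/T₂ are calibrated on out-of-fold benchmark scores; they
  inherit the benchmark's composition bias, as in any supervised
  calibration.
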