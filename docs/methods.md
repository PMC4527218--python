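# Methods

This note documents the models, estimators, numerical choices, and the
synthetic-data generators behind `scwga`, and what the test suite does and
does not establish about real data.

## Golden-control genotype model

The comparison baseline for all genotype metrics is a *golden control*: a
consensus genotype set from bulk sequencing (one table, or the concordant
intersection of two replicate bulks to suppress sequencing error) restricted
to positions on a SNP array. Restriction is positional by default; an
optional flag additionally requires the bulk genotype to equal the array
genotype, since either reading of "intersection with the chip" is defensible
and the positional one is the weaker assumption.

Genotypes are unordered allele pairs over {A,C,G,T}. Relative to the
reference base a genotype is HOMref (both alleles reference), HOMmut (both
alleles equal, non-reference) or HETref (exactly one allele reference). A
heterozygote with two non-reference alleles has no slot in this scheme; it is
rejected by default, or tagged with an internal `HETalt` label and excluded
from tabulated outputs (with a count) in permissive mode.

The concordance matrix is **control-anchored**: it iterates golden-control
sites only. A detected site contributes one count at
(single-cell category, control category, allele-share level), where the share
level is the multiset intersection size (2/1/0) of the two allele pairs.
Sites called in the cell but absent from the control are out of the matrix's
scope; they surface in the SNV metrics as false-positive candidates.

* CGDE (coverage) per control category: detected / control total.
* Consistency per single-cell category: share-2 count / detected in that row.
* Overall values are ratio-of-sums, not means of ratios.

## SNV accuracy

Against a bulk SNV set with zygosity:

* **FP**: single-cell SNVs at positions without a bulk SNV. The FP *ratio*
  divides the FP count by a genome-site constant G (default 3×10⁹,
  configurable) — an FP-per-genotypable-site rate, not an FP fraction of
  calls.
* **ADO**: bulk heterozygous sites where the covered cell is homozygous for
  one of the bulk alleles. The ADO *ratio* is
  ADO / (detected-het + ADO): the fraction of recoverable heterozygous sites
  that lost an allele. This denominator is the one that reproduces all three
  published per-cell ratios from their printed counts; the bulk-het-count
  denominator does not.
* **Efficiency** is exposed twice: *gross* (detected/control) and *net*
  ((detected − FP)/control). Published per-class percentages are net, while
  the headline mean efficiency is gross; both are therefore first-class.
  Percentages are kept at full precision (the published tables truncate).

The `snv_metrics` table-level estimator needs hom-ref calls present in the
single-cell genotype table, otherwise drop-out of the alternative allele
(HETref → hom-ref) is invisible. The simulation-facing estimator
`ado_fp_counts` works directly on calls vs the generating control and is
exact against truth labels (see below).

## Synthetic generators

The generators define the study conditions; they are first-class, tested
code. All randomness flows from one integer seed through a single numpy
`Generator` per call — same seed, byte-identical output.

**Golden control**: positions sampled uniformly without replacement per
chromosome (multinomial allocation by length), categories multinomial with
requested proportions, reference and alternative bases uniform.

**Single-cell calls**: per site, independently — uncovered with probability
1 − `site_coverage`; a covered HETref site suffers ADO with probability
`ado_rate` (retained allele uniform by default; a flag biases retention to
the reference, since drop-out is sometimes defined asymmetrically); a
covered, non-ADO site gains a spurious substitution with probability
`fp_rate`. The spurious base is drawn uniformly among bases *absent from the
control genotype at that site*: if it were merely "different from the
replaced allele", an FP on a het site could recreate a homozygous call
indistinguishable from ADO, and truth labels could not be scored exactly.
With this choice the estimator's ADO/FP counts equal the truth-label counts
exactly, which the suite asserts. One truth label per site
(uncovered/ADO/FP/faithful); FP draws are skipped on ADO sites so labels stay
exclusive.

**Binned counts**: count ~ Poisson(μ · a_b · N_b/2), with a_b log-normal
with log-s.d. `bin_dispersion` and **unit median** (log-mean 0), and N_b the
length-weighted truth copy number over the bin. Unit median (not unit mean)
keeps the modal ratio anchored, which is what mode normalization assumes. No
generative form for amplification bias is established in the field's
measurements — any heavy-tailed positive mixing law would do; log-normal is
this package's choice. Dispersion presets order the three chemistries as
observed on real data: DOP-PCR 0.15 < MALBAC 0.25 < MDA 0.6.

**Breakpoints**: the control set is the true breakpoints; the single-cell
set jitters each true end uniformly within ±50 bp — half the 100 bp matching
threshold, so true events stay matchable by construction — and adds
Poisson(`chimera_rate` × n_true) injected chimeras with types drawn from the
profile mix (defaults from observed chimera fractions, renormalized because
the printed percentages sum to 100.05). Same-chromosome chimeras get
exponential spans with scale `chimera_itx_length_scale` (default 5 kb:
neighbouring amplicons joining); CTX chimeras join two distinct,
length-weighted chromosomes at uniform positions.

What the generators do **not** emulate: read-level error, mappability and
alignment artifacts, locus-specific (e.g. GC-coupled) drop-out, linkage
between neighbouring sites, or chimeras that mimic true variants. Passing
recovery suites therefore shows the estimators are correct under the stated
stochastic model, not that the pipeline is robust to every real-data
pathology.

## Coverage uniformity

Normalized depth is window depth over the width-weighted genome mean; the
weighted mean of the output is exactly 1. Windows shorter than half the
nominal width (default 100 kb) are dropped from summaries — chromosome-end
runts otherwise add edge noise. Whether sex chromosomes belong in the genome
mean is left to the caller (`autosomes_only` flag; default includes all
supplied windows). GC strata use strict inequalities (> 0.50 HighGC,
< 0.35 LowGC, ties MiddleGC). The duplication-ratio denominator is mapped
reads, matching common practice. The Poisson reference draws n normalized
deviates from Poisson(λ)/λ with defaults λ = 30, n = 1000.

## CNV pipeline

* **Bins**: n bins (default 10,000) never crossing chromosome boundaries;
  equal-width per chromosome, or equal-weight quantiles when a mappability
  weight track is supplied (deserts absorbed into flanking bins).
* **Spike-in**: Ks = round(Kr × R), R length-weighted over partial bin
  overlap (the per-region formulation does not address bin straddling; length
  weighting is the continuous extension). A flag draws Poisson(Kr × R)
  instead for stochastic realism.
* **Normalization**: ratio = count/mean; with bin GC available, a lowess
  trend of count vs GC (frac 0.3) is divided out first. Whether the original
  pipelines kept GC correction is not always stated; it is a flag, default
  on.
* **Segmentation**: circular binary segmentation. For each segment the arc
  (i, j] maximizing a pooled-variance t statistic between in-arc and out-arc
  means is located by a full scan (windowed in 1000-bin panes for long
  segments, halving stride). Significance is a permutation test at
  α = 0.01 with 1000 permutations, where *both* the observed and permuted
  maxima are taken over a restricted family of arcs whose lengths lie on a
  ~40-point geometric grid: under exchangeability the p-value is exact for
  that family, and the grid makes each permutation O(n·40) instead of O(n²).
  The full-scan argmax (not the grid argmax) supplies the changepoint
  locations. Early stopping accepts once the exceedance count forces
  p > α. Zero-variance (noise-free) segments shortcut: a constant segment is
  never split, and an arc with zero pooled variance but nonzero mean
  difference is treated as infinitely significant, which makes noise-free
  changepoint recovery exact. Deterministic given the seed.
* **Mode normalization**: Gaussian-KDE mode m of the per-bin segment ratio
  over autosomes; copy number = 2 × ratio/m, invariant under global
  rescaling. In tetraploid-like bimodal profiles the heavier mode wins — by
  design, and worth flagging downstream.
* **Calling**: gain CN ≥ 2.5, loss CN ≤ 1.5 (midpoints between integer
  states — these thresholds are this package's choice, configurable),
  adjacent same-direction segments merged, minimum span 1 Mb.
* **Scoring**: L, L_C, L_T in bp over merged ≥ 1 Mb calls;
  sensitivity = L_T/L_C, specificity = L_T/L. Direction-agnostic by default
  (the length formulas reference no direction); a strict mode intersects
  gains with gains and losses with losses. Undefined denominators report as
  not-applicable, never 0. Interval arithmetic is BED-style 0-based
  half-open throughout; genotype tables alone are 1-based.

## Chimera matching

"Not further apart than 100 bp" is applied to **both** ends (the stricter
reading; a single-end mode is flagged). Ends are canonicalized
(lexicographic chromosome order, ascending position) before distances are
computed, so CTX matching compares unordered chromosome pairs. Matching is
greedy one-to-one — each control breakpoint validates at most one single-cell
breakpoint — ordered by smaller total end distance, ties broken by genomic
order, which makes the labelling deterministic and input-order invariant.

## Statistics

Mann-Whitney-Wilcoxon uses the exact U null distribution when both groups
have ≤ 20 observations and the pooled sample is tie-free, otherwise a
tie-corrected normal approximation with continuity correction (crossover
configurable). An all-identical pooled sample returns p = 1 with a warning.
Bonferroni is min(1, p·m); Pearson requires n ≥ 3 and nonzero variances.

## Problem sizes and test design

The suites run on synthetic data at desk scale, chosen once: genotype
recovery at 10⁵ sites over a 5-chromosome, 380 Mb example layout; the CNV
suite at 1,000 bins with four embedded regions (copy numbers 0, 1, 3, 4
spanning 15–26 bins each) and mean 200 reads/bin; chimera recovery at ~10⁴
injected junctions; segmentation null calibration on 100 seeded 1,000-bin
Poisson tracks. Spike-in truth regions sit on bin boundaries because the
spike-in itself operates per bin — off-grid regions only re-measure boundary
quantization, not pipeline accuracy. CNV sensitivity/specificity under
dispersion is aggregated as the mean over seeds, matching how per-cell
accuracies are conventionally averaged; the copy-number-3 region is near the
detection boundary at MALBAC-like dispersion and bin counts this small, so
individual seeds legitimately miss it.

## Known limitations

* The restricted-arc permutation family trades a little power for speed;
  very short aberrations (< min_width bins) are invisible by construction.
* Mode normalization is unidentifiable under genome-doubling; it reports the
  mode it used (`mode_ratio`) rather than guessing ploidy.
* The FP substitution spectrum is uniform over admissible bases; real
  amplification errors are biased (e.g. C→T).
* `snv_metrics` treats positional absence from the bulk set as the FP
  criterion; a genotype-mismatch criterion at shared positions is the
  concordance matrix's job, not this estimator's.
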