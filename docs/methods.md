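# Methods

This note documents the models, conventions, and numerical choices behind
`strpop`, in the spirit of a methods supplement. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model and conventions

A call set is a loci × samples matrix of diploid repeat-count genotypes.
Each call stores the unordered allele pair (canonicalized sorted), total
read depth, read-class support (enclosing / spanning / flanking), a 95%
confidence interval per allele, and a quality score in [0, 1].

- **Coordinates** are 0-based half-open internally; VCF POS is converted
  on I/O and BED is consumed natively. This makes interval arithmetic
  (segdup overlap, binning, windows) unambiguous.
- **Allele lengths are repeat units** everywhere. Base pairs are
  `repeats × motif length` when needed; mixing the two units is a common
  source of error, so one canonical unit is used throughout.
- **Motifs are 2–6 bp.** Mononucleotide runs and longer units are out of
  scope: genome-wide short-read STR genotypers do not call them reliably.
- **Major-allele ties** break toward the smaller repeat count so outputs
  are deterministic.
- **Variance convention** is population variance (denominator N),
  matching spectrum-as-distribution semantics.
- **Dosage** has two modes: `deviation_sum` `(a−ref)+(b−ref)` (the
  association dosage, canonical) and `repeat_sum` `a+b` (the LD dosage).
  They differ by the constant `2·ref_repeats` per locus, so correlations,
  regression slopes and p-values are identical under either mode; both
  are kept because the two analyses are conventionally described with
  different offsets.

## Synthetic cohort generator

The generator exists so every pipeline stage can be validated against
known ground truth; it is first-class, tested code.

**Allele frequencies.** Each locus has a founder repeat count (uniform
on 8–20 by default, matching typical reference repeat numbers of 2–6 bp
loci). A population's allele distribution is a symmetric geometric
("discrete Laplace") spread around its founder:
`P(step = k) ∝ σ^|k|`, truncated to repeat counts ≥ 1 and renormalized.
This is the simplest distribution consistent with the stepwise mutation
model, under which STR mutations add or remove small numbers of whole
repeat units. σ defaults to 0.3, which produces heterozygosities around
0.5–0.7 — the regime of informative genome-wide pSTRs. Population
structure is induced by shifting each population's founder with an
independent geometric step of scale `divergence` (0 = panmixia).

**Genotypes and QC metadata.** Diploid genotypes are two independent
draws per sample (Hardy–Weinberg within population). Depth is Poisson
with mean 30 — the scale of ~30× whole genomes — clipped into the
QC-pass range [20, 1000] for defect-free calls so the backbone is clean
by construction. A configurable fraction of called genotypes (default
1%) is planted with exactly one defect each — depth < 20, depth > 1000,
enclosing-read support zero, or a maximum-likelihood allele outside its
CI — and recorded in a truth table before any other noise. Missingness
is independent per call (default 2%).

**Trios.** Children inherit one uniformly chosen allele per parent; with
probability `de_novo_rate` an inherited allele takes a ±1 repeat step.
Each event is recorded together with a flag saying whether the mutated
allele escapes both parental allele sets (a step can land on another
parental allele and remain Mendelian-consistent; the flag makes
recovery tests exact).

**LD-linked SNPs.** A SNP in target LD with an STR is built by mixing
the standardized STR dosage with independent Gaussian noise and cutting
the latent variable into three genotype classes; the mixing weight is
calibrated by bisection against the realized sample `r²`. Realized `r²`
typically lands within ~0.05 of the target; discretization to three
levels bounds the maximum achievable `r²` below 1 unless the STR dosage
itself has three (equally spaced) levels, in which case target 1 is hit
exactly. The realized value is recorded in the truth table.

**Expression / PDUI.** Feature values are `β·dosage + covariate effects
+ N(0, noise_sd)`; `bounded=True` squashes through a logistic into
[0, 1] to emulate PDUI (distal poly(A)-site usage) indices. Planted β
values are recorded; pure-noise features can be appended for FDR
calibration.

**Genome layouts.** Chromosomes have equal p and q arms around a 3 Mbp
centromere. Loci are placed uniformly except that density in the
outermost 5 Mbp of every arm is multiplied by `telomeric_factor`,
giving a planted subtelomeric enrichment with known fold.

**What the generator does not emulate:** genealogical (coalescent)
allele-frequency structure, linkage between STR loci, locus-specific
mutation-rate variation, motif-sequence effects, and read-level error
processes. Passing tests therefore demonstrate correctness of the
statistical machinery on a faithful parametric model of multiallelic
STR variation, not robustness to every artifact of real sequencing data.

**Randomness.** One global seed expands into per-operation substreams by
stable hashing of the operation name (CRC-32 into a `SeedSequence`).
Adding randomness to one stage never perturbs another, which is what
makes pipeline stage toggles independent and runs byte-reproducible.

## QC filtering

Order is fixed: call-level filters first (failing genotypes become
missing), then samples below 50% call rate are dropped, then locus-level
filters run with call-rate denominators taken over the surviving
samples. Filtering is idempotent.

The Hardy–Weinberg test is an exact two-sided binomial test of the
observed heterozygous-sample count against `Binomial(n, 1 − Σ p̂ᵢ²)`
with allele frequencies pooled over both alleles of every genotype.
For highly multiallelic loci a genotype-table chi-square is
ill-conditioned (most cells near-empty); the heterozygote-count summary
remains well-behaved at any allele count. The test runs on the pooled
analysis cohort by default; a grouping option tests within each sample
group and removes the locus if any group fails (pooling diverged
populations deflates heterozygosity — the Wahlund effect — so grouped
testing is preferable when cohorts are strongly structured).

Segdup overlap uses any-overlap (≥ 1 bp) of the repeat tract, the
conservative reading. Surviving loci with more than one observed allele
are pSTRs, otherwise mSTRs; pSTR + mSTR + removed partitions the input.

## Trio and concordance metrics

Mendelian consistency is phase-free: both orderings of the child's
allele pair are tried against the parents' allele sets. The per-trio
rate's denominator counts loci where all three members are called; the
overall value is the unweighted mean of per-trio rates. Loci failing QC
in any member simply drop out of the denominator (the alternative —
requiring QC-pass in all members before counting — coincides here
because filtered calls are missing).

Caller-versus-caller concordance uses maximum multiset matching:
`c = |shared alleles| / 2`, so `{10,10}` vs `{10,12}` scores 0.5 (one
shared copy; the shared allele is never double-counted) and homozygote
agreement `{10,10}` vs `{10,10}` scores 1.

## Chromosome-context analyses

Subtelomeric enrichment bins each arm into 1 Mbp windows, calls the
outermost 5 Mbp subtelomeric, and compares mean bin counts
(fold = subtelomeric / other). The permutation test exchanges bin values
across positions and recomputes the fold; the empirical p is the
fraction of 10,000 permutations with fold ≥ observed. The exchange scope
is global across all non-acrocentric arm bins by default, with a per-arm
option (the appropriate scope depends on whether arm-level count
differences should count as signal); the scope is reported in the
output. Acrocentric p arms are excluded.

The meta-chromosome profile uses 100 kb chromosome-grid bins (bins
overlapping a centromere removed), an 11-bin centered rolling mean with
shrunken windows at chromosome edges (dropping edge bins would discard
the telomeric signal, the analysis target), arm-normalized positions
(−1 p-telomere … 0 centromere … +1 q-telomere) cut into 500 uniform
intervals, and normalization of the curve by its own mean. Contexts
(telomeric |pos| ≥ 0.95, centromeric ≤ 0.05, interstitial otherwise) are
tested against fold 1 with a two-sided one-sample t-test, Bonferroni
over the three contexts, α = 0.05.

## LD, tagging, enrichment

`r²` is the squared Pearson correlation between STR repeat-sum dosage
and SNP dosage over complete-case samples; constant vectors give an
undefined (NaN, never 0) result. Pairs are restricted to 250 kb;
samples whose unordered STR genotype occurs fewer than three times in
the cohort are dropped first (rare genotypes are disproportionately
errors and act as leverage points). A pair with `r² ≥ 0.7` is tagged;
per-STR summaries report the maximum `r²` over SNPs and the union of
tagging SNPs' traits. Catalog loading filters to p ≤ 5e-8 and drops
SNPs associated only with strongly environmentally confounded traits
(educational attainment, mathematical ability, intelligence;
configurable).

Tag enrichment resamples |focal| loci from the tested universe without
replacement and reports `p = #(resampled tag count ≥ observed)/n`. The
≥ convention is the standard conservative empirical p-value; it agrees
with the hypergeometric tail within Monte-Carlo error.

## QTL association and hierarchical FDR

Feature values are first residualized on known covariates by OLS
(intercept included; rank-deficient designs are rejected naming the
collinear columns). Hidden-factor estimation is not part of the
package: covariates are an input, which keeps the association stage
testable in isolation.

The scan pairs each feature with every STR whose tract lies within
500 kb of the feature's annotated span (distance 0 inside the span —
the inclusive reading, since anchoring to the TSS versus the gene body
is a modeling choice with no clear winner). Per-locus filters run in a
fixed order: ≥ 50 called samples, heterozygosity ≥ 0.1 on the analysis
cohort, unordered genotypes seen < 3 times removed, locus discarded if
fewer than 3 distinct genotypes remain. The genotype-count filter runs
on unordered genotypes before dosage conversion. A simple linear
regression of adjusted value on deviation-sum dosage gives slope, SE
and the two-sided t-test p per pair; dropped loci are logged with
reason codes.

Multiple testing is hierarchical: within each feature, Bonferroni by the
number of STRs tested for it, take the minimum; across features, BH on
those minima; features with q < 0.1 are significant and each reports
exactly one best pair (argmin p, ties toward the smaller coordinate), so
significant pairs and significant features are in bijection. The
permutation control shuffles the feature matrix's sample identifiers
once and re-runs the scan; its p-values are uniform when the machinery
is correct.

## Population analyses

Two observation conventions coexist in STR work and are applied
section-by-section:

- **Combined per-individual lengths (a+b)** for the rank-sum length
  comparison and for Rst: `Rst = (St − Sw)/St` with St the population
  variance of combined lengths pooled over all individuals and Sw the
  unweighted mean of within-group variances. Rst is undefined (NaN)
  when St = 0. Per-motif-length summaries are unweighted means over
  loci. A `pooled_alleles` option treats each allele as a separate
  observation instead.
- **Pooled alleles (two observations per sample)** for allele-length
  variance/SD summaries: highly variable loci (top 5% of within-group
  variance, ties at the cutoff included, heterozygosity > 0.1 required),
  the SD-difference permutation test (labels shuffled between groups
  with each sample's two alleles traveling together; empirical
  p = #(|perm diff| ≥ |observed|)/1000; BH across loci, α = 0.01), and
  expansion scores.

Rank-sum comparisons use the asymptotic normal approximation with tie
correction and continuity correction (repeat counts always tie), BH
across loci, significance at adjusted p < 0.01.

Expansion scores use linear-interpolation percentiles (the common
default; the convention is recorded here because order-statistic
percentile definitions differ): score = (P95 − median)/median of pooled
allele lengths, expanded at score ≥ 2.

PCA removes loci with major allele frequency ≥ 0.95, mean-imputes
missing dosages per locus, centers columns, and takes scores from SVD
with a deterministic sign convention (largest-magnitude loading
positive). STR diversity is the mean pairwise count of differing
genotype multisets within a population (pairs skip loci missing in
either member); SNP heterozygosity is the per-sample heterozygous
bi-allelic SNP count over the genome length considered. Saturation
curves draw k samples without replacement (k = step, 2·step, …, N) and
count loci polymorphic within the draw.

## Pipeline

`strpop all --config cfg.yaml --seed S --outdir out` runs
simulate → filter → stats → trio → density → ld → qtl → popgen, writing
every table as TSV plus a manifest (seed, stage list, config hash, row
counts). All thresholds default to the analysis values above. The
synthetic cohort is regenerated in memory for any stage selection, which
keeps stage toggles independent; file-based inputs enter through the
library readers (`read_str_vcf`, `read_intervals`, `read_sample_meta`,
`read_trios`, `read_gwas_catalog`) for users with real call sets.

Demo problem sizes (3 populations × 200 samples × 2000 loci; 10,000
layout loci and permutations for the density stage; permutation stages
capped at 300 loci; diversity on 40 samples per population) were chosen
so a full run completes in well under a minute on one core while every
stage still has enough data to be statistically meaningful. Null-
calibration tests use 200–400 permutations per instance over 50 seeds —
enough granularity for a Kolmogorov–Smirnov uniformity check without
excessive runtime.

## Known limitations

- Frequencies are parametric, not genealogical; no linkage between STR
  loci, so LD structure exists only where explicitly planted.
- The HWE binomial test treats estimated allele frequencies as known;
  at very small sample sizes this is mildly anti-conservative.
- The SNP generator's three-level discretization bounds achievable `r²`
  for highly multiallelic STR dosages.
- Interruption-aware allele modeling, sex chromosomes, and
  mononucleotide repeats are out of scope.
- `locus_concordance` assumes the two call sets index the same loci in
  the same order (the caller-comparison use case).
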