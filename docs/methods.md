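# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Coordinates and containers

All positions are 1-based physical bp with closed intervals. The *span* of an
interval is `end − start`, matching the "block distance" convention of the
pattern tables the package emits and parses (it excludes the first base; a
one-SNP interval has span 0). BED output converts explicitly to 0-based
half-open. Genotypes are alt-allele dosages in {0, 1, 2} with a distinct
missing sentinel (−1); phased haplotypes are two rows per sample. QC applies
strict (>) thresholds — variant call rate 0.90, MAF 0.05, sample call rate
0.95 — in the order samples → variant call rate → MAF (recomputed), with the
pass repeated to a fixed point so the filter is idempotent; the order is a
package choice and is recorded in the QC report.

## Mixed-model association

The EMMAX-style approximation: eigendecompose the kinship matrix once,
profile the REML log-likelihood of the null model over `log δ`
(grid −10…10 step 0.5, then bounded Brent refinement), and test every SNP by
GLS in the whitened basis with a t-test on n−2 degrees of freedom. Binary
status is coded 0/1 and analysed as quantitative. Missing genotypes are
mean-imputed per SNP for testing only. With an identity kinship matrix the
procedure reduces exactly to ordinary least squares, which the suite verifies
to 1e−6. Kinship has two modes: IBS allele sharing `(2 − |g_i − g_j|)/2`
averaged over pairwise-complete sites (used for relatedness pruning:
greedy removal of the sample in the most above-threshold pairs, ties broken
by mean kinship then id), and a VanRaden-centred GRM (used as the random
effect). The published analysis used a commercial IBD estimator with
unstated settings; IBS/GRM are fully specified substitutes serving the same
roles, not a re-implementation of that tool.

Adaptive permutation permutes phenotype labels in batches (default 1000),
counts `permuted ≥ observed` with a 1e−12 tie tolerance, and reports the
add-one estimate `p = (1+k)/(1+n)`. A SNP stops permuting once its exceedance
count reaches `drop_count` (default 10, the Besag–Clifford sequential rule):
at that point the estimate's relative error is already small for any p-value
far from the significance threshold. The default statistic is the allelic
trend t²; any statistic closure can be supplied.

## LD, blocks, and pattern tests

Two-locus haplotype frequencies come from the standard EM over the
double-heterozygote ambiguity (convergence 1e−8 in frequency, cap 1000
iterations). With no double heterozygotes the ML solution equals the phased
counts exactly; with them it may differ slightly — the suite tests both
regimes. D′ confidence intervals are profile likelihoods on a 101-point grid
over |D′| with allele frequencies fixed at their EM estimates; the 5th/95th
CDF crossings give the interval. Gabriel-rule constants are the Haploview
defaults (strong LD: CI low ≥ 0.70 and high ≥ 0.98; strong recombination:
high < 0.90; a block needs ≥ 95% strong-LD among informative pairs), pairs
farther than 1000 kb are skipped, candidate endpoints must themselves be in
strong LD, and candidates are accepted greedily longest-first. Pattern tests
are 2×2 Pearson chi-squares (pattern vs. rest on case/control chromosome
counts) without continuity correction; permutation moves both chromosomes of
a sample together, preserving within-individual phase correlation. Each
pattern is counted against its own statistic (not the familywise maximum).

## ROH

Runs are called in SNP-index space by a greedy left-to-right scan; with the
default zero tolerances a run is a maximal stretch of consecutive homozygous
calls, and heterozygous/missing tolerances are available because practical
callers allow slippage. Runs are trimmed to homozygous endpoints and never
overlap within a sample. The frequency track is the exact per-variant count
of covered subset samples divided by the subset size; the peak interval is
the smallest interval containing every variant within `rule × max` of the
peak.

## EHH / |iHS|

EHH uses the pair-counting definition with the denominator taken over the
chromosomes still informative at the extension (a chromosome with a missing
call inside the span is excluded from that extension outward, not globally).
iHH integrates EHH over physical bp by the trapezoid rule, truncating at the
first of: EHH below 0.05 (the first sub-cutoff point is included), 5 Mb from
the core, or the chromosome end; the truncation reason is recorded.
Integration is physical-distance-based because no genetic map accompanies the
data this mirrors; the simulator's constant cM/Mb makes the two equivalent up
to a factor. Ancestral alleles are assigned by the higher-frequency-in-cases
rule of the original analysis (ties break to the panel major allele); this
inverts the usual outgroup convention, so the sign of iHS should be
interpreted relative to that rule — |iHS| is unaffected. Standardization
bins by derived-allele frequency (20 equal-width bins, bins under 5 scores
merged into their nearest populated neighbour) and z-scores within bins;
window averaging is a centred 30-SNP moving mean over defined scores with
truncated edges. The hot inner loops (EHH group refinement, IBS window
counting) have numba kernels that replicate the reference Python
implementations bit-for-bit in logic; the Python paths remain and are what
the oracle tests exercise.

## IBS consensus

Windows slide with stride 1 (the analysis this mirrors "partitioned" the
chromosome without stating a stride; stride is a parameter). A window
supports the phenotype-bound consensus when some exact pattern has in-group
frequency ≥ 0.4 (the expectation for a dominant allele at intermediate
frequency; the threshold is tunable, its derivation is not re-litigated
here) and out-group frequency ≤ 0 by default ("never seen in controls";
relaxable). Missing calls exclude a chromosome from a window rather than
wildcard-matching — conservative against false sharing. Passing windows
across all window sizes merge into maximal regions; this merge rule is a
package choice since the source analysis only partially specifies how window
sizes were combined. Between-group sharing reports the largest window size at
which an identical pattern reaches the required frequency in both groups;
homozygote consensus verifies homozygosity inside the hint region (a
heterozygous call is an error naming sample and position), splits at
disagreeing homozygous sites, returns the longest side (alternatives
reported) and extends outward while agreement persists.

## Evidence integration

Association and ROH intervals are *span* tracks and are intersected; the
|iHS| peak (a point) and IBS regions (narrow sub-intervals) are *support*
tracks, classified as overlapping or failing but not intersected — otherwise
a point peak would collapse the consensus to nothing. A strict
all-intersection mode exists behind a flag. Reported lengths are rounded to
0.1 Mb; raw bp are always retained. An empty span intersection is an explicit
no-consensus result, not an exception.

## The synthetic cohort

The generator emulates the study design the pipeline targets, not cattle
demography:

* Ancestral SNP frequencies Uniform(0.05, 0.95); per-breed frequencies
  Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) with F = 0.15 per breed
  (typical of diverged cattle breeds). Founder haplotypes are drawn site-wise
  and partially smoothed by copying random long segments (expected length
  n_snps/20) from an 8-haplotype template pool with probability 0.5 per
  segment. Full smoothing would inflate Hudson FST by ≈ (1−F)/8; the partial
  scheme keeps the realized FST within a few hundredths of F while still
  inducing local LD.
* Meiosis: Haldane model, crossovers Poisson with mean equal to the map
  length (1 cM/Mb × 40 Mb = 0.4 Morgans), breakpoints uniform, no
  interference.
* The causal allele enters as one founder haplotype (single shared origin by
  default; independent per-breed origins available) at founder frequency
  0.05, and carrier breeds evolve under a smooth breeder-selection
  controller: carrier parents are preferred with weight exp(s·(target−f)/0.25)
  (s = 0.5) while the allele frequency f is below the managed band
  (0.45–0.65), neutral inside it. This reproduces a selective sweep with
  frequency held intermediate — the regime that makes a dominant coat trait
  mappable — and produces the decaying flanking haplotype sharing that ROH
  and |iHS| detect. A breed missing the band after 40 generations is redrawn.
* Defaults: 8 breeds + 2 backcross lineages ≈ 122 samples, 4,000 SNPs on
  40 Mb, 80 founder haplotypes and 200 breeding individuals per breed,
  40 generations. Backcrossing transmits a carrier-selected gamete against a
  fresh recipient each generation, so expected donor ancestry is 2^−g
  (tracked exactly via ancestry labels).
* Dominant penetrance (default 1.0) maps carrier status to phenotype;
  missingness can be injected post hoc (default 0) to exercise QC.

What it does **not** emulate: realistic mutation/recombination heterogeneity,
genotyping error, ascertainment bias of SNP arrays, X chromosomes, or real
breed history (population sizes and ages are chosen for detectability).
Passing the recovery suite therefore shows the pipeline recovers a planted
dominant locus under idealized but structurally faithful conditions; it does
not certify performance on real array data.

## Problem sizes in the test and acceptance runs

Unit tests use cohorts of a few hundred SNPs and tens of samples. The
parameter-recovery suite runs the default cohort (≈122 samples × 4,000 SNPs)
across 20 seeds with the span evidence tracks (association + ROH), the two
that define the consensus interval; support tracks are exercised on single
seeds elsewhere in the suite. Calibration uses 2,000 independent null SNPs
for type-I error and 20,000 draws for |iHS| standardization. The pipeline's
default ROH peak rule is 0.75-of-max: for a dominant locus held at
intermediate frequency q, locus homozygosity among affected animals is
bounded near q/(2−q) while hitchhiked flanking segments can slightly exceed
it, so demanding 0.9-of-max would make peak localization knife-edge;
`peak_interval`'s own default remains 0.9.

## Known limitations

* The mixed model is the approximation, not per-SNP REML (available behind a
  flag, at cost); logistic mixed models are out of scope.
* Haplotype stages require phased input; the simulator emits true phase, and
  real unphased data must be phased externally.
* Permutation p-values for patterns are per-pattern, not familywise.
* The bundled pattern table's Results-derived summary contains one internal
  inconsistency in its source (the block labelled longest in prose is not the
  longest by the table's own start/end arithmetic); `pattern_table_stats`
  reports the arithmetic truth.
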