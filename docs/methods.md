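# Methods

This note documents the statistical definitions, numerical conventions and
design choices behind sweepscan, and what the synthetic-data generator
does and does not emulate.

## Data model and coordinates

Genotypes are diploid allele-count codes (0/1/2 copies of `allele_b`,
−1 missing) over a SNP map sorted by (chromosome, position); phased
haplotypes are binary rows paired per sample, with no missing values
(phasing is an upstream step — the package accepts phased VCF and the
simulator emits truth haplotypes; it does not phase). Coordinates are
1-based inclusive internally. Interval length is `end − start` — the
arithmetic that applies when an interval is quoted by its bounding SNP
coordinates — and kb lengths truncate (floor). BED output converts to
0-based half-open.

When two genotyping platforms cover the same region, sources are merged
by (chromosome, position) with allele harmonization (swapped alleles flip
codes, `c → 2 − c`); at conflicting calls the designated primary platform
wins, and a concordance report over overlapping non-missing genotype
pairs is returned. SNPs with irreconcilable allele coding are excluded
and logged.

## Quality control

The cascade is: sample missingness filter, then locus missingness filter,
then per-SNP filters. Thresholds are strict ("more than 30%" missing
excludes a sample; defaults 30% samples / 15% loci, 10% MAF, HWE alpha
2×10⁻⁴). The missingness-curve helper suggests a cutoff as the argmax of
the discrete second difference of the exclusion count (the knee after
which exclusions change linearly), ties broken toward the smaller
threshold; it is advisory only, because knee-finding on real curves is a
judgement call — filters always take explicit thresholds.

Hardy–Weinberg testing uses the exact conditional test (enumeration of
heterozygote counts given allele counts, summing configurations no more
probable than the observed), which is robust at breed sample sizes of a
few dozen where the chi-square approximation is not. The test is applied
within each breed separately; pooled testing would produce Wahlund-effect
false exclusions precisely at the differentiated SNPs a selection scan
cares about. MAF is computed over all samples pooled.

X-chromosome analyses use females only — male and female effective
population sizes differ on X, and hemizygous males would distort both
Hardy–Weinberg and homozygosity-run statistics. Samples of unknown sex
are dropped with a warning; a breed with no females is an error.

## FST estimators

* **Wright (basic form)**: F_ST = (H_T − H_S)/H_T with H_S the unweighted
  mean of the breeds' expected heterozygosities and H_T evaluated at the
  unweighted mean frequency. Bounded in [0, 1]; undefined (NA) at SNPs
  monomorphic overall.
* **Weir–Cockerham**: the two-population θ = a/(a+b+c) with the standard
  sample-size correction, using diploid sample sizes and observed
  heterozygote frequencies. Negative estimates at undifferentiated SNPs
  are reported as-is (not clipped) — they are part of the estimator's
  sampling distribution — but percentile thresholds are computed on
  Wright values.
* **Hudson**: 1 − H_w/H_b with the unbiased within-population
  heterozygosity 2pq·n/(n−1) on allele counts and
  H_b = p₁(1−p₂) + p₂(1−p₁).

The three differ in how they weight sample size and correct sampling
noise; at equal breed sizes over a neutral background their per-SNP values
correlate at r > 0.99 (a property the test suite checks on 5,000 simulated
SNPs). Note one consequence of the definitions: at identical finite-sample
frequencies Wright is exactly 0 while Weir–Cockerham and Hudson are
slightly negative (their unbiased corrections subtract the expected
sampling contribution).

Windowed F_ST is a centered sliding mean of 5 adjacent SNPs (step 1), NA
members dropped, windows never spanning chromosomes, incomplete edge
windows NA. Centering matches per-SNP plotting; the window size of five
markers is the scale at which chip-density scans show multi-marker signal
without washing peaks out.

## Runs of homozygosity

For one animal at one SNP the statistic is the length of the maximal run
of consecutive homozygous genotypes containing that SNP — zero when the
SNP itself is heterozygous, NA when it is missing. Missing calls
terminate runs (conservative: no-calls never inflate a run), and runs
truncate at the boundaries of the analyzed window. The scan reports the
per-breed median over animals, evaluated over the candidate region
extended by 25 SNPs of flank so that runs near the region edge are not
artificially clipped.

## EHH, iHS and XP-EHH

EHH at distance d from a core SNP is the probability that two random
haplotypes carrying the specified core allele are identical at every SNP
from the core out to d (all-pairs identity count over nested intervals;
identity classes only ever split outward, so EHH is non-increasing — an
invariant asserted on every profile). For the cross-population variant
the "carriers" are all haplotypes and the profile starts at the
single-site homozygosity of the core.

iHH integrates the decay trapezoidally against **physical distance (bp)**
outward per direction until EHH first falls below 0.05, the crossing
linearly interpolated, both directions summed. No genetic map is assumed
— chip-scale sheep data has none — so iHH carries bp·EHH units; this is
the usual physical-map approximation of the centimorgan integral and is
inconsequential for iHS/XP-EHH because the units cancel in the log-ratios.
Profiles that reach the region edge above the cutoff are flagged
edge-truncated and retained by default (a flag drops them); no gap
penalty is applied at large inter-SNP spacings.

uiHS = ln(iHH_A/iHH_D) is computed per breed for every SNP with a known
ancestral state, within-sample MAF ≥ 0.10 and at least two carriers of
each core allele. Standardization subtracts the bin mean and divides by
the bin SD within 18 derived-allele-frequency bins — equal-width over
[0.05, 0.95] by default ("equally sized" bins are read as equal frequency
width; equal-count binning is available behind a flag). X-flagged SNPs
are binned and standardized in a separate pass, since the X's distinct
demographic history shifts the uiHS distribution. Bins with fewer than
two SNPs or zero spread yield NA. |iHS| is reported as a 10-SNP sliding
mean assigned to the window's center-right SNP, NA members dropped —
10 SNPs rather than the ~40 used on dense human panels, reflecting the
longer LD extent and wider SNP spacing of sheep chip data.

XP-EHH at SNP i integrates each population's whole-sample EHH to the same
boundary per direction — the point where the **pooled** two-population
EHH first drops below 0.05, so both integrals cover the same interval and
the ratio is not driven by differing truncation. The raw score
ln(I_A/I_B) is z-scored over all scored SNPs; positive values mean
unusually long haplotypes (a sweep) in population A. SNPs without an
ancestral assignment are excluded from iHS but retained for XP-EHH, which
needs no polarity.

Pairwise r² is D²/(p_i q_i p_j q_j) from phased haplotype counts. Core
haplotypes over a selection peak are enumerated as distinct allele
strings per breed with exact count-based frequencies, sorted by pooled
frequency (ties lexicographic); published-style display rounds to two
decimals and can dash-compress against the top haplotype, and a pooling
helper aggregates haplotypes below a frequency floor (default 0.02) into
an "other" remainder, as such tables conventionally do.

Ancestral states can be inferred from a user-supplied cross-species
allele table: if exactly one of the SNP's alleles appears across the
outgroups it is ancestral; otherwise a majority vote weighted by inverse
divergence rank decides (closer outgroups outvote distant ones — e.g.
four ungulates/carnivores carrying C outvote human T), exact ties and
empty evidence returning unknown. Observations matching neither SNP
allele are ignored with a log message. Running the alignments that
produce the species table is out of scope; the table is an input.

## Interval refinement

Candidate intervals are maximal runs of consecutive SNPs passing a
threshold, spanning the first to last passing SNP's positions (interval
ends are the outermost passing SNP coordinates, not midpoints to
neighbours). Thresholds are strict (`value > threshold`, or |value| for
two-sided statistics). NA SNPs break runs by default; a bridging flag
lets chip gaps pass through without fragmenting intervals. F_ST
thresholds default to empirical percentiles of the scan (99.9 autosomal /
99.0 X, nearest-rank definition: the ⌈q·n/100⌉-th smallest value, chosen
for cross-implementation reproducibility); the |XP-EHH| threshold
defaults to the fixed 4.34 convention from genome-scale human scans and
should be lowered for desk-scale scans where a z-score cannot reach it.
Union and intersection combine evidence across statistics; multi-interval
chromosomes report per-interval and summed lengths.

## Synthetic data

The generator emulates the study design the statistics assume: two breeds
of 45 diploids (37 females, 8 males), jittered ~25 kb SNP spacing, and
background allele-frequency differentiation produced by the
Balding–Nichols model — each breed frequency drawn
Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral frequency p ~
U(0.1, 0.9). The ancestral allele is the major allele of the ancestral
draw, so derived alleles start rare, consistent with sweep logic.

`background_fst` is the **measured** differentiation target: with only
two populations the basic Wright index estimates total heterozygosity
from the two-population mean and therefore recovers about F/2/(1−F/2) of
the drift parameter F, so the generator calibrates F = 2t/(1+t) to make
the mean per-SNP Wright F_ST across neutral SNPs equal the requested t
(default 0.024, a typical genome-wide background for closely related
breeds). Parameter recovery within ±0.01 over 10,000 SNPs is a test.

Background SNPs are in **linkage equilibrium**: alleles are drawn
independently per SNP. Only the implanted sweep creates LD — a chosen
fraction (carrier frequency, rounded half-up to whole haplotypes with a
largest-remainder reconciliation) of one breed's haplotypes is replaced,
over a SNP span, by a single haplotype composed of the derived allele at
every span SNP. This isolates the haplotype statistics' signal and keeps
the generator analytically checkable, but it means passing tests
demonstrate sensitivity to a clean, recent, hard sweep on an LD-free
background — not performance under realistic recombination, demography,
soft sweeps or genotyping error. There is deliberately no coalescent or
forward simulation here; users wanting realistic backgrounds should
generate data with a simulator built for that and feed the phased VCF in.

An exact fixture builder realizes a published-style core-haplotype
frequency table as a concrete population: dash-coded rows are expanded
against haplotype 1, counts are round(freq·n) with largest-remainder
correction so each breed totals exactly n (frequency columns may sum to
1 ± 0.02, the slack of two-decimal rounding). Feeding the fixture back
through enumeration reproduces the input frequencies to within 1/n.

## Determinism and problem sizes

All randomness flows through a single integer seed per generator call;
fixed seed and config give byte-identical pipeline outputs. The test and
acceptance workloads use desk-scale sizes — 2,000-SNP scans for
standardization moments, 5,000 SNPs for estimator agreement, 10,000
frequency draws for drift recovery, 50 seeds for sweep detectability —
chosen so the whole suite runs in well under a minute of simulation per
property while keeping Monte-Carlo error far below the tested tolerances.

## Known limitations

* No phasing, imputation, relatedness pruning or assembly liftover;
  coordinates are treated as opaque labels.
* Haplotype-block calling (Gabriel-style confidence intervals) is not
  implemented; pairwise r² is the LD surface provided.
* The linkage-equilibrium background understates multiple-testing
  correlation between adjacent windows relative to real chip data.
* Whole-genome empirical percentiles (99.9th of tens of thousands of
  SNPs) are meaningful only on genome-scale input; on a few hundred SNPs
  the nearest-rank percentile collapses to the maximum and the fixed
  |XP-EHH| threshold is unreachable — thresholds are configurable for
  that reason.
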