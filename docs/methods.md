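# Methods

## Scope

`exomir` analyzes exosomal small-RNA sequencing experiments with a
two-condition (control vs EtOH), two-timepoint (E16/E19), two-batch
(Exp1/Exp2) design: single-end 50 nt reads from libraries in which sample
RNA was mixed with 1/15 of its amount of spike-in RNA before library
construction. Because the real libraries are not shipped with the package,
a synthetic-data generator with machine-readable ground truth is a
first-class component; every stage is validated against it.

## Read-level processing

**Adapter trimming.** The 3' adapter (default `AGATCGGAAGAGC`, the ligation
adapter family of common small-RNA prep kits; configurable) is located by
semi-global matching: candidate matches either place the whole adapter
inside the read or overlap the read's 3' end with an adapter prefix. A
match is accepted when errors/overlap ≤ 0.1 and overlap ≥ 3; ties are
broken by fewest errors, then longest overlap, then earliest cut. Matching
is repeated on the trimmed read until no acceptable match remains, which
makes trimming idempotent. The trade-off is deliberate: with error-tolerant
suffix matching, an insert whose own 3' end resembles the adapter prefix
(~2% of random inserts at the 3-base minimum overlap) is trimmed slightly
short. The batched implementation vectorises the scan across a whole
library and is verified base-for-base against the scalar reference in the
test suite.

**Quality trimming** uses the running-sum rule: the read is cut at the
suffix start minimising Σ(q − cutoff) over the suffix (empty suffix
allowed), cutoff Q20. **Length filter:** 15–45 nt, inclusive, with an
attrition report.

## Alignment

A small, exact reimplementation of mismatch-mode ("-v") short-read
alignment with best-stratum reporting. Candidate placements come from
pigeonhole seeding — the read is cut into v+1 disjoint pieces, one of which
must match exactly; exact piece hits are retrieved from per-length k-mer
tables over the forward strand (the reverse strand is searched with the
reverse-complemented read). Every candidate is verified by direct mismatch
counting. With `best_strata` on, only the minimal-mismatch stratum is
reported; placements are ordered canonically (chromosome, start, strand
+ before −) and truncated to k = 100. `n_placements` — the n of the 1/n
counting rule — is the stratum size **before** truncation, capped at k:
this matches what a consumer of the aligner's output can observe. Reads
shorter than the seed length (12) are unmapped, not errors. No indels, no
quality-aware scoring; genome-scale performance is a non-goal (genomes here
are ~100 kb). On such genomes the aligner is tested for exact placement-set
equality against a brute-force all-offset scan.

## Annotation assignment and counting

piRNA annotations published on an older assembly are lifted through UCSC
chain files (target side = source assembly). An interval is lifted only
when ≥ 95% of its bases map through a single chain; strand flips are
applied for reverse-strand chains, and rejections carry a reason.

A placement is assigned to a mature locus when strands match and its
strand-oriented 5' end lies within [-3, +2] nt of the annotated 5' end and
its 3' end within [-2, +3] nt of the annotated 3' end (both inclusive).
Windows are strand-oriented rather than genomic-left/right because mature
small-RNA end heterogeneity is a property of the 5'/3' ends of the RNA,
not of chromosome coordinates. A placement satisfying the windows of two
or more annotations is credited to the one with the smallest
|5' offset| + |3' offset|; exact ties split the mass equally and are
counted in the run log. Each read distributes 1/n per assigned placement
(n = `n_placements`); loci sharing a species id (multi-copy species)
accumulate into one matrix row. Spike-ins are counted by exact sequence
identity (no mismatches), separately from genomic alignment.

## Normalization and differential expression

Normalization composes in a fixed order. First the spike-in/total-mapped
correction: each library is scaled to reads-per-million mapped and then by
its spike-in rate relative to the cross-sample mean rate (equivalently,
counts are divided by f_s ∝ spike_s / mean_rate). This makes a library
duplicated at twice the depth normalize identically and anchors absolute
scale to the spike-ins. Second, median-of-ratios size factors over species
with all-positive counts (species containing zeros are excluded from the
reference set, as is standard for this estimator). Both classes use size
factors computed on the **miRNA** submatrix: miRNAs normalize themselves,
and piRNAs are normalized with the miRNA species' counts, with miRNA rows
removed before piRNA testing — the class-specific scheme this analysis
prescribes.

The per-species model is NB with log link and size-factor offsets, fitted
by Fisher-scoring IRLS at a fixed dispersion (initialised from the offset
log mean, step-clipped, 100 iterations, tolerance 1e-8; non-converged or
singular fits are flagged and keep a missing p-value rather than being
dropped). The condition coefficient is reported as log2 fold change with
Wald z = β/SE and a two-sided normal p; BH q-values are computed within
each tested set. Candidates are flagged on **raw p < 0.05** — the selection
rule used for downstream qPCR validation — with q-values reported alongside
and a switch to flag on q instead. Timepoints are analyzed as independent
two-group contrasts; the batch can optionally enter as an additive
covariate (both modes provided because the original handling is not
derivable from the study description).

**Dispersion.** Raw dispersion is the within-group method-of-moments
estimate α̂ = (s² − μ̄)/μ̄², pooled across groups with df weights. The
trend a₀ + a₁/μ is fitted by trimmed least squares on the *signed*
estimates (the signed moment estimator is unbiased for the true
dispersion, so mean-targeting regression calibrates the trend; gross
outliers are removed over three reweighting rounds). Final dispersions
shrink log raw toward log trend with a weight derived from the residual
spread (MAD²) against the approximate sampling variance of a log
dispersion estimate (trigamma((m − p)/2)), floored at 1e-8. Species whose
moment estimate is zero or negative carry no dispersion information and
take the trend value. This is a deliberately simplified empirical-Bayes
scheme; exact numerical parity with Cox–Reid-based packages is a non-goal.
Its calibration is what the acceptance suite checks: type-I error within
[0.03, 0.07] at nominal 0.05 (n = 3 vs 3, α = 0.05), sensitivity ≥ 0.8
with 100% sign agreement for |log2fc| = 2.

**Class enrichment.** Per sample, summed normalized counts per class
(or detected-species richness, both provided); the paired piRNA − miRNA
differences feed a two-sided paired t test with a 95% CI of the mean
difference. Zero-variance nonzero differences report p below machine
precision with a degenerate-variance warning.

## Clustering and reporting

Sample profiles are log2(normalized + 1); Pearson correlation; average-
linkage agglomeration on 1 − r (heights are monotone; the tree is
deterministic, and seeded permutations affect only p-values). The
label-association score is mean within-label minus mean between-label
correlation, with a seeded permutation p; labels with one sample are
excluded from the within-label mean with a warning. Note that for a
balanced two-label design the label swap always reproduces the observed
score, so the smallest attainable permutation p is ≈ 2/C(2k, k), not
1/(N+1). Candidates are species with p < 0.05 ranked by p, then |log2fc|,
then species id, truncated to 12.

## qPCR statistics

ΔCt = Ct(target) − Ct(reference) with technical replicates averaged first
(reference assay RNU1A by default); samples missing the reference are
excluded with a warning. Fold change is E^−ΔΔCt with amplification
efficiency fixed at E = 2.0 (configurable; no standard-curve calibration).
Group comparisons run on the ΔCt scale by one-way ANOVA (with two groups,
F equals the squared pooled t statistic exactly); error bars are standard
errors.

## The synthetic-data generator

The generator emulates: random ~100 kb genomes with ~40 nt repeat
cassettes pasted at 4 locations each (creating genuine multi-mapping;
a species planted inside a cassette is annotated at every copy under one
species id); 50 miRNA (20–24 nt) and 200 piRNA (26–31 nt) loci on both
strands, non-overlapping per strand, 20% inside cassettes; 8 spike-in
sequences (21–23 nt) screened to have no exact genome match (the
commercial spike-in composition is proprietary, so these are synthetic
stand-ins); and 50 nt reads built as mature sequence + end jitter +
substitution errors (0.1%/base) + adapter read-through.

Per-end offsets are drawn independently from P(0)=0.60, ±1=0.10, ±2=0.05,
±3=0.04, ±4=0.01 — deliberately placing some mass outside the assignment
windows so the filtering is exercised; no read-end error model is claimed
beyond this.

Counts: per-species rates are Gamma(1/α, mean·α) around
base · 2^(fc·[EtOH] + batch shift), followed by a single multinomial of
size `depth_per_sample` including spike-ins at expected share 1/16 (the
15:1 mass ratio). Marginals are therefore gamma-Poisson
(negative-binomial-like) conditioned on the exact library total — chosen
so that per-sample read totals are exactly conserved, which a plain
independent-NB draw cannot guarantee. Baseline abundances are log-normal
(σ = 1) with 75% of genomic mass assigned to piRNAs (piRNA dominance
holds in every sample). The batch effect is a per-(species, batch)
Gaussian shift on log2 mean with sd 0.5; treatment affects only planted
species (defaults: six miRNAs at ±2 and three piRNAs, echoing the handful
of condition-responsive species the analysis is meant to recover). These
defaults make batch dominate treatment in the correlation structure of
the full count matrix in ≥ 90% of replicates.

Ground truth records every emitted read (source species, applied offsets,
number of exact genomic placements of its error-free sequence) plus exact
and expected per-species counts. With zero jitter, zero error and no
adapter, the complete trim→align→quantify chain reproduces the truth
count matrix **exactly**; this end-to-end oracle is part of the test
suite.

What the generator does **not** model: ligation/sequence bias, RNA
secondary structure, UMIs, exosome biogenesis, indel errors, or
non-uniform quality strings. Passing tests therefore demonstrate
correctness of the analysis logic under the stated statistical model, not
robustness to every artefact of real libraries.

## Problem sizes and runtime choices

Tests and the acceptance script run on desk-scale data chosen to keep the
whole suite in minutes on one CPU: genomes of 100 kb, 250 species,
libraries of 6k–50k reads (200k reads total for the exact-recovery
oracle), 200 replicates for power studies, 100 for the clustering study,
2000 species for type-I calibration. Real studies at ~10M reads/library
per-sample would use the same code paths with an external aligner via the
SAM interface.

## Known limitations

- The aligner is O(genome) in memory per seed length and is not intended
  for mammalian-genome scale; the SAM interface exists to swap in a
  production aligner with the same reporting contract.
- Dispersion moderation is simplified (see above); p-values at n = 3 are
  approximately, not perfectly, calibrated (measured type-I ≈ 0.06–0.07
  at nominal 0.05).
- The liftover mapper handles block-structured chains with single-chain
  images; it does not resolve images split across chains (such intervals
  are rejected, with a reason, rather than guessed).
- Candidate selection encodes only the stated rule (p < 0.05, ranked by p
  and |log2fc|); any visual/manual curation of candidates is out of scope.
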