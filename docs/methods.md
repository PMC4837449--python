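# Methods

`allelepipe` detects allele-specific binding (ASB) and expression (ASE) at
heterozygous SNVs by comparing read counts between the two haplotypes of a
personal diploid genome. This note documents the statistical model, the
procedural choices made where the design was genuinely open, what the
synthetic-data generator does and does not emulate, and the problem sizes
used in the shipped checks.

## Model

At a heterozygous SNV with `n` informative reads, let `K` be the number of
reads carrying the reference allele. Under the null of no allelic imbalance,

    K ~ BetaBinomial(n, a, b),   a = b = (1 - rho) / (2 rho),

with mean fixed at 1/2 and overdispersion `rho = 1/(a + b + 1)`; `rho = 0`
is the plain binomial limit. The two-tailed p-value doubles the smaller tail
and is capped at 1 — the construction under which total imbalance
(`k in {0, n}`) at `p <= 0.05` first becomes reachable at **six reads**
(`2 * 0.5^6 = 0.03125`), the floor applied throughout. For computational
efficiency, sites with `n >= 1000` are rescaled to `n = 1000` preserving
the allelic ratio.

### Overdispersion estimation

`rho` is estimated per data set by least sum of squared errors (LSSE)
between the empirical allelic-ratio histogram (sites with `n >= 6`, one
equal-weight entry per site) and the null histogram implied by a candidate
`rho` over the same multiset of read depths: a coarse grid
`rho in {0, 0.1, ..., 1}` followed by bisection refinement of the
bracketing interval, shrinking it by comparing LSSE at the two interior
midpoints until narrower than `1e-4` (at most 30 iterations). The estimator
is deterministic.

Open choices resolved here:

- **Binning**: 51 equal-width bins on [0, 1]. An odd bin count keeps 0.5 off
  the bin edges, so the central mass is not split; with half-open bins, a
  ratio landing exactly on an interior edge goes to the right bin — both the
  empirical and the expected histogram use the same rule, so the LSSE
  comparison is consistent even where binned symmetry is not exact.
- **Grid endpoint**: at `rho = 1` the beta shapes vanish; the implementation
  uses the limit distribution (mass 1/2 at each of `k = 0` and `k = n`) so
  the grid endpoint is evaluable.
- **Weighting**: each SNV contributes equally to the empirical histogram,
  not proportionally to its read count.

Data sets whose `rho` reaches the flag threshold are dropped before pooling:
0.125 for RNA-seq, 0.3 for ChIP-seq (both configurable; the comparison is
`>=`). High overdispersion usually signals uneven or sparse coverage rather
than biology.

### Simulation-based FDR

Power varies with per-site depth, so multiple testing is corrected by
explicit simulation rather than a p-value-only procedure: each iteration
reassigns every read at every tested site by a fair coin and recomputes the
same beta-binomial test (with the estimated `rho`). At a candidate threshold
`t`, `FDR(t) = (mean simulated positives at t) / (observed positives at t)`;
the cutoff is the largest observed p-value with `FDR <= target` (5% RNA-seq,
10% ChIP-seq), ties included. 100 iterations by default. When no threshold
qualifies, zero calls result — a legitimate outcome on null data.

**Accessibility**: a site is statistically detectable only if total
imbalance could reach the cutoff, giving a data-set-specific minimum depth
`N = min{n : p(n, n; rho) <= cutoff}`; accessible SNVs have
`n >= max(6, N)`, and their non-significant subset is the matched control
set for enrichment. Using the extreme case underestimates accessibility and
therefore yields conservative enrichment p-values.

## Mapping bias

Two biases are addressed. **Reference bias** — reads carrying the alternate
allele start one mismatch behind when mapped to a haploid reference — is
removed by aligning to both personal haplotypes and keeping the
fewer-mismatch alignment (ties broken by a seeded coin; reads multimapped
in any reported alignment, or needing more than two mismatches, are
dropped).

**Ambiguous mapping bias (AMB)** arises from sequence homology: reads
carrying one allele match a paralogous locus and vanish into multimapping
(unique-mapping aligners report nothing for them), while reads carrying the
other allele map cleanly, leaving a spurious imbalance. The filter works
per read: every uniquely mapped read overlapping 1-5 het SNVs (an "O read")
is expanded into all `2^h - 1` alternative allele combinations ("S reads"),
which are re-mapped to the *other* haplotype with the same mismatch budget
and uniqueness rule. The O read is removed if any S read multimaps
(`amb_multi`) or maps uniquely away from the lifted equivalent position
(`amb_displaced`); O reads whose observed base matches neither allele are
removed as probable sequencing errors (`seq_error`). O reads over more than
5 het SNVs are dropped (`excluded_complex`). S reads that fail to map at
all do not trigger removal (logged `s_unmapped`). The filter is idempotent
and never removes whole sites, so genuine allele-specific signal at a
biased locus survives in the reads that remain.

## CNV filter

Copy-number changes masquerade as allelic imbalance. Windowed read depth
normalized to the genome-wide mean (1,000-bp windows for low-coverage
genomes, 100-bp for high-coverage) defines the filter: SNVs in windows with
normalized depth `< 0.5` or `> 1.5` are removed; the boundary values are
retained (strict inequalities). Only the depth-ratio rule is implemented
here; the depth track or alignments it is computed from are inputs.

## Enrichment, MAF spectra, motifs, trio

- **Enrichment** compares allele-specific against control SNVs per
  annotation with Fisher's exact test (two-sided hypergeometric p; sample
  odds ratio `ad/bc`, `NA` when undefined). Two counting modes: *collapsed*
  (one record per unique site across the cohort; AS in any individual wins)
  and *expanded* (one record per site-individual occurrence,
  population-aware). Bonferroni correction uses the number of annotations in
  the run. Classification from the corrected test: `p <= 0.05` with
  `OR >= 1.5` is *allele-specific*, `p <= 0.05` with `OR < 1.5` is
  *balanced*, otherwise *indeterminate* (NA odds ratios are indeterminate).
- **MAF analysis** bins minor allele frequencies at width 0.005 and tests
  rare (`MAF <= 0.005`) vs non-rare against AS vs control in a 2x2 Fisher
  table; `OR < 1` means AS sites are depleted of rare variants.
- **Motif disruption**: for an ASB SNV in a TF motif, the occurrence
  difference is the PWM frequency of the reference allele minus that of the
  alternate at the SNV's motif position (strand-aware; positive favours the
  reference allele). A 59-bp window (±29 bp) around the SNV is also
  rescanned on both strands with each allele substituted at the centre,
  reporting matches whose sum-of-log-likelihood score reaches an exact
  p-value `<= 1e-6`; this captures motif-gaining alleles. Score p-values
  come from exact dynamic programming over per-position score distributions
  discretized at `1e-3` log-likelihood units (validated against exhaustive
  enumeration for short motifs); background is uniform 0.25 per base by
  default, and PWM columns get a `1e-3` pseudocount before the log.
  Disruption is summarized by the Pearson correlation of occurrence
  difference with allelic ratio.
- **Trio inheritance**: at SNVs allele-specific in both members of a pair
  (heterozygous in all three members, or heterozygous in the compared pair
  and homozygous in the third), similarity of reference-allele ratios is
  summarized by Pearson's `r` — preferred over the regression slope as the
  single-trio stand-in for heritability — with the slope of child on parent
  reported alongside. Oppositely-directed sites are retained; they correctly
  lower `r`.

## Synthetic-data generator

The generator produces a random reference, phased het SNVs (optionally het
indels), and reads drawn from the two haplotypes so that each site's
reference-allele proportion follows a beta-binomial around its true ratio
with configurable `rho`; sequencing errors are injected per base. Sites are
spaced at least two read lengths apart so every read overlaps one SNV,
making per-site counts exactly the beta-binomial draws the detection null
assumes — a closed loop for parameter recovery. An optional engineered
paralog copies one SNV's neighbourhood (carrying the alternate allele) to
another locus with a block of three adjacent divergent bases offset from
the SNV; reads whose window misses the divergence multimap and are
suppressed, reproducing genuine one-sided AMB whose magnitude is controlled
by the divergence offset.

The built-in aligner is an exhaustive Hamming-distance scan (≤2
substitutions, forward strand, best-stratum uniqueness, multimapped reads
suppressed). It exists for fixture genomes only and mirrors how
unique-mapping short-read aligners silently drop ambiguous reads — the
behaviour the AMB filter depends on. Not emulated: paired ends, base
qualities, fragment-length/GC/mappability structure, indel-containing
alignments, reverse-strand reads. Passing tests therefore demonstrate the
statistics and bookkeeping, not robustness to those real-data features.

## Problem sizes in the shipped checks

Overdispersion recovery uses 50,000 sites at depth 50 per generating `rho`
in {0, 0.05, 0.1, 0.2, 0.4} (recovered within ±0.02, typically ±0.003).
FDR calibration and power use 50 replicates (1,000 null sites at depth 30;
2,000 null + 50 planted sites at ratio 0.95, depth 100), 40 simulation
iterations each. The AMB fixture uses 8 het SNVs at depth 200 on a 10-kb
genome. The read-level fixtures are kilobase-scale because the exhaustive
aligner is quadratic; the statistics are depth- and count-driven, not
genome-length-driven, so this loses no generality for the properties
checked.

## Known limitations

- Autosomal diploid logic only; no sex-chromosome ploidy handling.
- Overlapping variants on a haplotype are rejected, not merged; indels are
  applied as given (no re-normalization).
- Multi-allelic VCF records contribute only their first ALT.
- The null simulation reassigns reads with a fair coin (not beta-binomial
  resampling); the test applied to those draws carries the estimated `rho`.
- The FDR simulation pools sites of all depths rather than stratifying.
- Peak calling, CNV genotyping and real-data alignment are consumed as
  inputs (BED, depth track, SAM/BAM), not performed.
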