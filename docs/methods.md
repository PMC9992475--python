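# Methods

This note documents the models, conventions and design choices behind
`amplimhc`, in the spirit of the methods documentation of simulation and
statistics packages. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The genotyping problem and the filter cascade

The pipeline consumes an amplicon-sequence-variant (ASV) table: exact,
denoised sequence variants with read counts per amplicon, as produced by a
standard denoising pipeline. Upstream read processing (demultiplexing,
trimming, merging, denoising) is out of scope. The cascade applies, in a
fixed order:

1. **Coverage floor** — amplicons with fewer than `min_reads_per_amplicon`
   (default 100) total reads are discarded (`discarded_low_coverage`).
   Thresholds phrased "less than" are exclusive.
2. **Count floor** — variants whose *dataset-wide* maximum per-amplicon
   count is below `min_variant_max_count` (default 10) are removed. The
   maximum is evaluated across the whole dataset, not per sample, since a
   real allele should be well supported somewhere.
3. **Off-target screen** — variants whose global-alignment p-distance to
   every reference allele exceeds `offtarget_max_distance` (default 0.40)
   are removed. This replaces a manual alignment plus similarity-search
   step; 0.40 comfortably clears inter-locus divergence on the amplicon
   while excluding non-homologous sequence.
4. **Frequency floor** — the per-amplicon variant frequency (PAVF) is
   recomputed on the reads retained after steps 1–3, so that artefact
   frequencies cannot be diluted by off-target reads, and occurrences
   below `min_pavf` (default 1%) are dropped. PAVF is not recomputed again
   after later steps.
5. **Within-amplicon artefacts** — chimera detection first, then
   point-artefact detection, both against *surviving* higher-frequency
   variants of the same amplicon:
   - a chimera is any variant exactly equal to a single-breakpoint
     concatenation of two distinct parents, both with strictly higher
     PAVF; parents must be co-occurring, and a variant identical to a
     parent never qualifies. The scan is a prefix/suffix match, valid
     because co-amplified alleles are length-matched in this system;
     chimeras between parents of unequal length are not scanned.
   - a point artefact is within edit distance 1 (one substitution or one
     1-nt indel) of a parent with PAVF(v) ≤ `parent_child_ratio` ×
     PAVF(p). The default ratio 1/3 separates heterozygote co-amplification
     (near 1:1 even under amplification bias) from error progeny (≪ 1:1);
     it is configurable because no canonical value exists.
6. **Cross-amplicon screen** — an occurrence with PAVF below
   `cross_amplicon_low` (default 5%, again a judgement call: "low
   frequency" has no canonical number) of a variant that survives at ≥5%
   in another amplicon is flagged as contamination. Replicates lacking the
   variant confirm the flag but do not change the reason code.
7. **Plausibility cap** — amplicons retaining more variants than
   2 × (loci per primer set) are marked `unclear`; their surviving variants
   remain listed so downstream users can inspect them. This operationalizes
   an "unclear genotype profile", which is otherwise undefined.

Every variant occurrence ends exactly once — called, or rejected with one
of seven reason codes — and the cascade asserts this audit completeness.
Raising `min_pavf` can only shrink call sets (monotonicity, property-tested).

Replicate concordance compares called allele sets between all unordered
pairs of amplicons of the same individual and primer set (n replicates give
n(n−1)/2 comparisons).

## The synthetic experiment

The generator emulates the statistical structure the cascade assumes, not
read-level sequencing chemistry (no quality models, no index-hopping
mechanics beyond a flat contamination rate).

- **Allele pool.** A random in-frame ancestor (81 codons) is mutated into
  per-locus founders on a star topology, giving pairwise founder
  divergence ≈ `locus_divergence` (default 0.30 substitutions/site,
  matching the scale of between-locus divergence in real multi-locus MHC
  systems); within-locus alleles are mutated from the founder to pairwise
  divergence ≈ `within_locus_diversity` (default 0.08, the scale of
  within-locus nucleotide diversity in such systems). All substitutions
  avoid stop codons in frame 0 by rejection sampling. With three or more
  loci, locus "C"'s founder carries a one-codon deletion three codons from
  the 3' end — the diagnostic deletion of the third locus. Configurations
  implying saturated divergence (expected p ≥ 0.75) are rejected.
- **Genotypes and CNV.** Each locus contributes two allele draws with
  replacement (so 1–2 distinct alleles) unless dropped entirely with
  probability `cnv_missing_prob` (default 0.15).
- **Primer sets.** Loci are paired two-per-primer-set with the odd locus
  alone (for 3 loci: PS1 co-amplifies A and B, PS2 amplifies C),
  mirroring the two-primer-pair design such systems use.
- **Read counts.** Per-amplicon depth is negative-binomial
  (gamma–Poisson; mean 3000, dispersion 5) — amplicon coverage is
  overdispersed in practice. Each allele carries a multiplicative
  amplification bias drawn log-uniformly from
  `allele_amplification_skew` (default 0.5–2×) once per experiment, so
  replicates share the bias: amplification efficiency is a property of the
  primer–template pair, which is what makes replicate-incongruent
  low-frequency variants interpretable as contamination rather than bias.
- **Artefacts.** The drawn depth is partitioned: contaminant reads
  (whole-amplicon event with probability `contamination_rate`, volume
  1.5–4% of depth, sequence = a registry allele absent from the
  individual's genotype), chimeric reads (binomial at `chimera_rate` when
  ≥2 parents co-amplify, concentrated into 1–3 distinct single-breakpoint
  forms, as PCR amplifies early-cycle chimeras), point-error reads
  (binomial at `error_rate`; one derivative per parent, 80% substitutions,
  20% 1-nt indels), and true-allele reads (multinomial with skew weights).
  Artefact counts are capped strictly below their parents' counts (surplus
  reads return to the parent), and all counts sum exactly to the drawn
  depth. Artefact sequences colliding with true alleles are re-drawn.
  Every injected artefact is recorded with a class label (chimera /
  point_error / contaminant) and its parents, enabling exact
  precision/recall scoring.
- Default artefact rates (5% chimeric reads, 2% error reads, 1%
  contaminated amplicons) are calibration choices representative of
  multi-template amplicon PCR, not estimates of any particular run.

## Locus assignment

Nearest-reference assignment by p-distance (global alignment, pairwise
deletion of gap columns). Ties within `tie_tolerance` (default 0.01, far
below realistic inter-locus margins) give `unassigned`. The diagnostic
deletion is detected by length: an allele ≥3 nt shorter than the
deletion-free references is deletion-bearing — optimal alignments do not
place gaps uniquely, but called alleles carry no other indels, so length is
the robust signal. A deletion-bearing allele nearest to a non-deletion
locus is a conflict → `unassigned`. Assignment is deterministic and
independent of panel order (distance ties between loci break
alphabetically, inside the tie tolerance anyway). Gene conversion between
paralogues can genuinely blur locus identity; the reported margin
quantifies, but does not model, that uncertainty.

## Diversity statistics

S, k and π use **complete deletion** of gap-containing columns — all pairs
are compared on the same site set, matching the convention of the classic
DNA-polymorphism software. π = k/L′ where L′ is the retained site count;
the reported `pi_sd` is the square root of Nei's (1987, eq. 10.7) total
variance (sampling + stochastic components) — stated explicitly because
tools differ in which variance they print next to π. Amino-acid p-distances use **pairwise
deletion** codon-wise: an in-frame alignment is translated codon-by-codon
('-' for gapped codons, 'X' for ambiguity, both excluded pairwise). The
reading frame is inferred by translating a reference in all three frames
and keeping the stop-free one. Alleles translating with an internal stop
are excluded from amino-acid distances with a warning — MHC amplicon
alleles are expected functional, so a stop signals an upstream problem.

## Selection (NG86 + Z-test)

Per codon, each position contributes one site split between synonymous and
nonsynonymous in proportion to the synonymous fraction of its non-stop
single-nucleotide changes, so s + n = 3 for every sense codon. Differences
between codon pairs are averaged over all minimal substitution pathways
avoiding stop codons (if every pathway hits a stop — possible for a few
distant pairs — the constraint is lifted for that pair). Codons with gaps,
ambiguity or stops in either sequence are dropped pairwise. Proportions are
corrected with Jukes–Cantor; p ≥ 3/4 raises a saturation error in the
scalar API and drops the pair from means in the vectorized path.

Partition means average dN and dS over all unordered allele pairs
restricted to the masked codons. Variances come exclusively from codon
bootstrap (resampling codon columns with replacement, default 1000
replicates, shared resamples for dN and dS); no analytical variance is
used. Z = (d̄N − d̄S)/√(Var d̄N + Var d̄S) with a one-tailed p from the
standard normal upper tail; identical sequences give Z = 0, p = 0.5 by
convention, and zero bootstrap variance with unequal rates reports a
boundary p with a warning.

The default peptide-binding-site mask ships as a data file of 1-based
amplicon codon indices, derived from the human HLA-DRβ1 peptide-contact
residue set of the DR1 crystal structure. The amplicon does not carry
domain numbering, so the mask assumes amplicon codon 1 ↔ β1 residue 5 (the
amplicon spans >93% of the exon, starting a few codons in); contacts beyond
the amplicon span are ignored at load time. This mapping is an assumption —
users with an anchored alignment should supply their own mask file.
Site-model ML analyses (M7/M8, BEB) are external-tool territory and not
reimplemented.

## Recombination

Biallelic, gap-free segregating sites are scanned for four-gamete
violations; Rm is the minimum number of breakpoints hitting every violating
open interval, computed by greedy stabbing of intervals sorted by right
endpoint (optimal for interval hitting; verified against exhaustive cover
in tests). Sites with gaps or more than two alleles are excluded.

The Phi test scores each pair of parsimony-informative sites (≥2 states
each seen ≥2 times) by its refined incompatibility — the minimum number of
extra mutations forced by the joint state pattern, computed as the cycle
count e − v + c of the bipartite state graph. The statistic is the mean
score over pairs at most `window` (default 100) alignment positions apart;
the p-value is the fraction of random site-order permutations with a
statistic ≤ observed (+1 correction). Scores are left unnormalized: with
mostly biallelic sites the normalization constant is 1, and the permutation
test is invariant to a common scale. Fewer than three informative sites, or
no pair within the window, returns a "not computable" result rather than an
error. Breakpoint attribution to specific recombinant alleles and
gene-conversion tract inference are out of scope.

## Rarefaction

Sampling is without replacement over individuals; for each n the mean and
SD over `reps` (default 500) draws are reported, per primer set and for the
cohort genotyped with every primer set. The closed-form expectation
E[A(n)] = Σ_a (1 − C(N−c_a, n)/C(N, n)) over alleles with carrier counts
c_a is exposed separately and used as the oracle in tests. No richness
extrapolation (Chao-type) is attempted.

## Problem sizes used by the test suite and acceptance script

The reference synthetic study is 40 individuals, 3 loci × 20 alleles,
depth 3000, 5%/2%/1% artefact rates, 6 replicated individuals — about 90
amplicons and 60 true alleles, the scale of a single-population MHC
screen. Calibration studies use deliberately compact designs: 500 neutral
alignments of 8 sequences × 30 codons with 200-replicate bootstraps for
the Z-test type-I check; 200 clonal coalescent alignments (12 haploid
samples, 200 bp, JC69 mutations at a rate high enough for recurrent
mutation, no recombination) with 199 permutations for Phi; 100
positive-selection and 50 founder-mosaic power replicates. These sizes
give binomial standard errors of ~1–1.5 percentage points on the
calibrated rates while keeping the full suite fast.

## Known limitations

- Chimera detection only scans equal-length parent pairs; systems with
  length-polymorphic co-amplified alleles would need an alignment-based
  breakpoint scan.
- The cross-amplicon screen cannot flag contamination by an allele carried
  by no sequenced individual at high frequency; such contaminants are
  instead usually caught by the frequency floor.
- Codon-wise translation assumes gaps respect codon boundaries, true for
  the generator and for codon-aware alignments, approximate for arbitrary
  nucleotide MSAs (gapped codons are simply excluded pairwise).
- The simulator's CNV model is a single per-locus dropout probability;
  real systems can show locus-specific and haplotype-structured CNV.
- Passing recovery tests on synthetic data shows the cascade is correct
  under its own assumptions (single-breakpoint chimeras, ≤1-edit errors,
  flat contamination); real data can violate them (multi-breakpoint
  chimeras, primer-site polymorphism, allele-specific dropout).
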