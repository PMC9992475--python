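# amplimhc

Genotyping and population-genetic characterization of duplicated MHC class
IIβ genes from deep amplicon sequencing.

## The problem

Classical MHC genes are the most polymorphic loci in vertebrate genomes and
typically occur as several recently duplicated copies. Amplicon-based
genotyping of such a system — here modelled on a shark MHC IIβ exon-2
system with three loci, two of them co-amplified by a single primer pair,
and copy-number variation among individuals — has to separate a handful of
true alleles per amplicon from a cloud of PCR/sequencing artefacts: chimeras
formed by template switching between co-amplified alleles, single
substitution/indel error variants riding on abundant parents, and
cross-sample contamination. `amplimhc` implements that artefact-filter
cascade over an amplicon-sequence-variant (ASV) count table, assigns the
validated alleles to loci, and computes the downstream population-genetic
statistics used to characterize such systems. A first-class synthetic-data
module generates whole experiments with known truth, so every step of the
pipeline is scored against ground truth rather than eyeballed.

It is aimed at molecular ecologists and immunogeneticists running
multi-locus MHC (or similarly duplicated) amplicon panels.

## What it computes

**Genotyping cascade** (per ASV table): amplicons with <100 reads are
discarded; variants with a dataset-wide maximum per-amplicon count <10 are
discarded; off-target variants are removed by p-distance to a reference
panel; the per-amplicon variant frequency PAVF(v,a) = n(v,a)/Σ_v n(v,a) is
recomputed on the retained reads and occurrences with PAVF < 1% dropped; a
variant is a *chimera* if it equals p₁[1..b] + p₂[b+1..L] for two
higher-frequency co-occurring parents, and a *point artefact* if it is within
edit distance 1 of a parent with PAVF(v) ≤ PAVF(p)/3; low-frequency
occurrences (<5%) of variants confidently called elsewhere are flagged as
contamination. Every rejection carries a reason code, replicate amplicons
are compared set-wise, and amplicons retaining more variants than their
primer set can yield (2 per locus) are flagged as unclear.

**Locus assignment**: nearest-reference p-distance with a tie tolerance, a
diagnostic 3-nt deletion forcing the deletion-bearing locus, and
copy-number summaries (alleles per individual per locus).

**Diversity**: segregating sites S, mean pairwise differences k, nucleotide
diversity π = k/L (complete deletion of gapped columns), and amino-acid
p-distances (pairwise deletion) within and between loci.

**Selection**: Nei–Gojobori (1986) counting of synonymous/nonsynonymous
sites and differences with Jukes–Cantor correction d = −¾·ln(1 − 4p/3),
averaged over all allele pairs on three codon partitions (all sites,
peptide-binding sites, non-PBS), with a one-tailed Z-test of dN > dS,
Z = (d̄N − d̄S)/√(Var d̄N + Var d̄S), variances from 1000 codon bootstraps.

**Recombination**: Hudson–Kaplan minimum recombination events Rm from
four-gamete-violating site pairs, and the pairwise homoplasy index (Phi)
permutation test.

**Rarefaction**: permutation allele-accumulation curves (500 draws per
sample size) with a closed-form hypergeometric expectation as cross-check.

## Worked example

```sh
amplimhc run-all --seed 1 --out demo/
```

prints

```
pipeline complete; replicate concordance 1.000; precision 1.000, recall 1.000
```

meaning: on the default synthetic study (40 individuals, 3 loci × 20
alleles, mean depth 3000, 5% chimeric reads, 2% error reads, 1%
contaminated amplicons, 6 replicated individuals) every replicate pair
received identical genotypes and every called allele is a true allele
(precision) with no true allele missed (recall). `demo/` then contains the
ASV table, genotypes, the full rejection audit, locus assignments, CNV
tables, and per-locus statistics; e.g. `recombination_summary.tsv`:

```
locus  rm  intervals                                            phi     phi_p  phi_computable
A      7   15-16;69-72;122-126;143-146;162-163;199-201;229-230  0.218   0.708  True
B      2   210-211;217-219                                      0.233   0.549  True
C      2   131-137;237-239                                      0.160   0.190  True
```

Rm is the four-gamete lower bound on historical recombination events with
the breakpoint intervals (1-based, inclusive); the Phi p-values are
non-significant, as expected for alleles simulated without recombination
(the non-zero Rm reflects recurrent mutation under the high simulated
diversity). Individual stages are available as `simulate`, `genotype`,
`assign-loci`, `diversity`, `selection`, `recombination` and `rarefaction`
subcommands; all coordinates in output TSVs are 1-based inclusive.

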