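"""Synthetic-data generator: structure, artefact bookkeeping, determinism."""

import itertools

import numpy as np
import pytest

from amplimhc._seq import translate
from amplimhc.simulate import (
    SimulationConfig,
    primer_sets_for,
    simulate_allele_pool,
    simulate_asv_table,
    simulate_experiment,
    simulate_genotypes,
)


def p_dist(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b)) / len(a)


def single_linkage_clusters(seqs, threshold):
    """Brute-force single-linkage clustering oracle on p-distance."""
    groups = [{i} for i in range(len(seqs))]
    merged = True
    while merged:
        merged = False
        for gi, gj in itertools.combinations(range(len(groups)), 2):
            if any(
                len(seqs[i]) == len(seqs[j]) and p_dist(seqs[i], seqs[j]) < threshold
                for i in groups[gi]
                for j in groups[gj]
            ):
                groups[gi] |= groups[gj]
                del groups[gj]
                merged = True
                break
    return groups


class TestAllelePool:
    def test_zero_within_diversity_gives_identical_alleles(self):
        cfg = SimulationConfig(within_locus_diversity=0.0, seed=1)
        reg = simulate_allele_pool(cfg)
        for locus in reg.founders:
            seqs = {reg.sequences[a] for a in reg.alleles_of_locus(locus)}
            assert len(seqs) == 1

    def test_three_locus_pool_recovers_three_clusters(self):
        cfg = SimulationConfig(n_loci=3, alleles_per_locus=20, seed=2)
        reg = simulate_allele_pool(cfg)
        assert len(reg.sequences) == 60
        # cluster at the midpoint between within- and between-locus divergence;
        # same-length sequences only (the C deletion already separates C)
        ids = sorted(reg.sequences)
        seqs = [reg.sequences[a] for a in ids]
        thr = (cfg.within_locus_diversity + cfg.locus_divergence) / 2
        groups = single_linkage_clusters(seqs, thr)
        assert len(groups) == 3
        for g in groups:
            loci = {reg.locus_of[ids[i]] for i in g}
            assert len(loci) == 1

    def test_deletion_locus_alleles_are_3nt_shorter(self):
        reg = simulate_allele_pool(SimulationConfig(seed=3))
        la = len(reg.sequences["DBB-A*01"])
        for a in reg.alleles_of_locus("C"):
            assert len(reg.sequences[a]) == la - 3

    def test_all_alleles_translate_without_stops(self):
        reg = simulate_allele_pool(SimulationConfig(seed=4))
        for seq in reg.sequences.values():
            assert "*" not in translate(seq)

    def test_founder_divergence_near_target(self):
        cfg = SimulationConfig(seed=5, locus_divergence=0.3)
        reg = simulate_allele_pool(cfg)
        d = p_dist(reg.founders["A"], reg.founders["B"])
        assert d == pytest.approx(0.3, abs=0.05)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"locus_divergence": 0.8},
            {"within_locus_diversity": 0.75},
            {"chimera_rate": 1.5},
            {"depth_mean": 0},
            {"n_loci": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            simulate_allele_pool(SimulationConfig(**kwargs))


class TestGenotypes:
    def test_no_cnv_gives_one_or_two_alleles_everywhere(self):
        cfg = SimulationConfig(cnv_missing_prob=0.0, n_individuals=20, seed=6)
        reg = simulate_allele_pool(cfg)
        truth = simulate_genotypes(reg, cfg)
        for g in truth.genotypes.values():
            for locus, alleles in g.items():
                assert 1 <= len(alleles) <= 2

    def test_missing_fraction_matches_binomial_oracle(self):
        # binomial: fraction of individuals lacking a locus ~ B(n, p)/n
        cfg = SimulationConfig(
            cnv_missing_prob=0.5, n_individuals=1000, alleles_per_locus=5, seed=7
        )
        reg = simulate_allele_pool(cfg)
        truth = simulate_genotypes(reg, cfg)
        missing = np.mean([len(g["A"]) == 0 for g in truth.genotypes.values()])
        se = np.sqrt(0.5 * 0.5 / 1000)
        assert abs(missing - 0.5) <= 3 * se

    def test_genotype_alleles_exist_in_registry(self):
        cfg = SimulationConfig(n_individuals=10, seed=8)
        reg = simulate_allele_pool(cfg)
        truth = simulate_genotypes(reg, cfg)
        for g in truth.genotypes.values():
            for alleles in g.values():
                assert set(alleles) <= set(reg.sequences)


class TestASVTable:
    def test_noise_free_table_contains_only_true_alleles(self):
        cfg = SimulationConfig(
            chimera_rate=0, error_rate=0, contamination_rate=0, n_individuals=10, seed=9
        )
        reg, truth, table = simulate_experiment(cfg)
        assert set(table.counts.index) <= set(reg.sequences)
        assert not truth.artefact_class

    def test_chimeric_read_fraction_matches_binomial_oracle(self):
        cfg = SimulationConfig(
            chimera_rate=0.05,
            error_rate=0,
            contamination_rate=0,
            depth_mean=3000,
            n_individuals=30,
            seed=10,
        )
        reg, truth, table = simulate_experiment(cfg)
        chim_ids = [v for v, c in truth.artefact_class.items() if c == "chimera"]
        total = table.counts.to_numpy().sum()
        chim = table.counts.loc[chim_ids].to_numpy().sum()
        # chimeras only arise in amplicons with >=2 co-amplified alleles, so
        # compare against the binomial expectation on those amplicons
        multi = [
            amp
            for amp in table.counts.columns
            if (table.counts.loc[list(set(table.counts.index) & set(reg.sequences)), amp] > 0).sum() >= 2
        ]
        eligible = table.counts[multi].to_numpy().sum()
        p_hat = chim / eligible
        se = np.sqrt(0.05 * 0.95 / eligible)
        assert abs(p_hat - 0.05) <= 3 * se + 1e-3
        assert chim < total

    def test_artefact_counts_below_their_parents(self, default_experiment):
        _, registry, truth, table = default_experiment
        counts = table.counts
        checked = 0
        for v, cls in truth.artefact_class.items():
            if cls not in ("chimera", "point_error") or v not in counts.index:
                continue
            parents = truth.artefact_parents.get(v, ())
            for amp in counts.columns:
                if counts.at[v, amp] == 0:
                    continue
                parent_counts = [
                    counts.at[p, amp] for p in parents if p in counts.index
                ]
                if parent_counts and all(c > 0 for c in parent_counts):
                    assert counts.at[v, amp] < min(parent_counts)
                    checked += 1
        assert checked > 10  # the default conditions inject plenty of artefacts

    def test_fixed_seed_reproduces_table_exactly(self):
        cfg = SimulationConfig(n_individuals=8, seed=11)
        _, _, t1 = simulate_experiment(cfg)
        _, _, t2 = simulate_experiment(cfg)
        assert t1.counts.equals(t2.counts)
        assert t1.sequences == t2.sequences
        assert t1.amplicons.equals(t2.amplicons)

    def test_replicate_amplicons_created(self, default_experiment):
        cfg, _, _, table = default_experiment
        reps = table.amplicons[table.amplicons["replicate"]]
        assert reps["individual"].nunique() == round(
            cfg.replicate_fraction * cfg.n_individuals
        )


def test_primer_sets_pair_loci():
    assert primer_sets_for(3) == {"PS1": ["A", "B"], "PS2": ["C"]}
    assert primer_sets_for(1) == {"PS1": ["A"]}
    assert primer_sets_for(4) == {"PS1": ["A", "B"], "PS2": ["C", "D"]}
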