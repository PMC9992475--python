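"""Synthetic multi-locus MHC amplicon data with known truth.

The generator emulates the statistical structure of a deep-amplicon MHC
class IIβ exon-2 genotyping experiment on a species carrying three divergent
loci: two loci co-amplified by one primer pair, a third amplified separately,
per-individual copy-number variation (a locus may contribute no allele),
skewed per-allele amplification, PCR chimeras between co-amplified alleles,
low-frequency single-substitution/indel error variants, cross-sample
contamination, and replicated individuals. Every injected artefact is
recorded with a class label so downstream filters can be scored against
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import (
    NUCS,
    STOP_CODONS,
    mutate_avoiding_stops,
    random_coding_sequence,
)

#: locus labels are letters; the last locus of a 3-locus system ("C") carries
#: the diagnostic 3-nt deletion near the 3' end of the exon.
LOCUS_LABELS = "ABCDEFGH"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated genotyping experiment.

    Defaults describe the reference scenario used throughout the test
    suite: 40 individuals, 3 loci x 20 alleles, mean depth 3000 reads per
    amplicon, 5% chimeric reads, 2% error reads, 1% contaminated amplicons
    and 6 replicated individuals (fraction 0.15).
    """

    n_individuals: int = 40
    n_loci: int = 3
    alleles_per_locus: int = 20
    locus_divergence: float = 0.30
    within_locus_diversity: float = 0.08
    cnv_missing_prob: float = 0.15
    depth_mean: float = 3000.0
    depth_dispersion: float = 5.0
    allele_amplification_skew: tuple[float, float] = (0.5, 2.0)
    chimera_rate: float = 0.05
    error_rate: float = 0.02
    contamination_rate: float = 0.01
    replicate_fraction: float = 0.15
    n_codons: int = 81
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "cnv_missing_prob": self.cnv_missing_prob,
            "chimera_rate": self.chimera_rate,
            "error_rate": self.error_rate,
            "contamination_rate": self.contamination_rate,
            "replicate_fraction": self.replicate_fraction,
        }
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.n_loci > len(LOCUS_LABELS):
            raise ValueError(f"at most {len(LOCUS_LABELS)} loci supported")
        # expected pairwise p-distance beyond ~0.75 is saturated for 4-state
        # characters and cannot be realised by substitution sampling
        if self.locus_divergence >= 0.75 or self.within_locus_diversity >= 0.75:
            raise ValueError("divergence at or beyond saturation (p >= 0.75)")
        if self.locus_divergence < 0 or self.within_locus_diversity < 0:
            raise ValueError("divergences must be non-negative")


@dataclass
class AlleleRegistry:
    """True allele pool: id -> sequence with locus labels and per-locus
    founder (reference) sequences."""

    sequences: dict[str, str]
    locus_of: dict[str, str]
    founders: dict[str, str]

    def alleles_of_locus(self, locus: str) -> list[str]:
        return [a for a, l in self.locus_of.items() if l == locus]


@dataclass
class TruthSet:
    """Ground truth for a simulated experiment.

    ``genotypes`` maps individual -> locus -> list of allele ids (0-2).
    ``artefact_class`` maps variant id -> one of
    ``{"chimera", "point_error", "contaminant"}``; true alleles never appear
    in it, and every non-true variant of the associated table appears
    exactly once.
    """

    registry: AlleleRegistry
    genotypes: dict[str, dict[str, list[str]]]
    artefact_class: dict[str, str] = field(default_factory=dict)
    #: variant id -> parental true-allele ids (2 for chimeras, 1 for point
    #: errors); empty for contaminant occurrences
    artefact_parents: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def true_alleles_of(self, individual: str, loci: list[str]) -> set[str]:
        g = self.genotypes[individual]
        out: set[str] = set()
        for locus in loci:
            out.update(g.get(locus, []))
        return out


@dataclass
class ASVTable:
    """Amplicon-sequence-variant table: read counts of exact sequence
    variants per amplicon, plus the variant sequences and amplicon metadata.

    ``counts``: DataFrame, rows = variant ids, columns = amplicon ids.
    ``amplicons``: DataFrame indexed by amplicon id with columns
    ``individual``, ``primer_set``, ``run``, ``replicate``.
    """

    sequences: dict[str, str]
    counts: pd.DataFrame
    amplicons: pd.DataFrame

    def validate(self) -> None:
        missing = set(self.counts.index) - set(self.sequences)
        if missing:
            raise ValueError(f"variants without sequences: {sorted(missing)[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate amplicon ids")


def primer_sets_for(n_loci: int) -> dict[str, list[str]]:
    """Pair loci onto primer sets: two loci per set, the odd one alone.

    For the 3-locus default this yields ``PS1 -> [A, B]`` (co-amplified) and
    ``PS2 -> [C]``, mirroring a system where one primer pair captures two
    paralogues and a second pair captures the divergent third locus.
    """
    loci = list(LOCUS_LABELS[:n_loci])
    sets: dict[str, list[str]] = {}
    for i in range(0, n_loci, 2):
        sets[f"PS{i // 2 + 1}"] = loci[i : i + 2]
    return sets


def _allele_name(locus: str, serial: int) -> str:
    return f"DBB-{locus}*{serial:02d}"


def simulate_allele_pool(config: SimulationConfig) -> AlleleRegistry:
    """Generate the true allele pool.

    Per-locus founder sequences sit at pairwise divergence approximately
    ``locus_divergence`` (star topology from a random in-frame ancestor);
    within-locus alleles at pairwise divergence approximately
    ``within_locus_diversity`` from each other. The third locus' founder
    carries a 3-nt (one codon) deletion near the 3' end. All alleles
    translate without stop codons in frame 0 and are pairwise distinct.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.n_codons * 3
    ancestor = random_coding_sequence(config.n_codons, rng)

    founders: dict[str, str] = {}
    for i in range(config.n_loci):
        locus = LOCUS_LABELS[i]
        n_subs = int(round(config.locus_divergence / 2 * L))
        f = mutate_avoiding_stops(ancestor, n_subs, rng)
        if config.n_loci >= 3 and locus == "C":
            # diagnostic 3-nt deletion: drop the third-to-last codon
            cut = (config.n_codons - 3) * 3
            f = f[:cut] + f[cut + 3 :]
        founders[locus] = f

    sequences: dict[str, str] = {}
    locus_of: dict[str, str] = {}
    seen: set[str] = set()
    for locus, founder in founders.items():
        n_subs = int(round(config.within_locus_diversity / 2 * len(founder)))
        for j in range(config.alleles_per_locus):
            for _ in range(200):
                allele = mutate_avoiding_stops(founder, n_subs, rng)
                if allele not in seen or n_subs == 0:
                    break
            name = _allele_name(locus, j + 1)
            sequences[name] = allele
            locus_of[name] = locus
            seen.add(allele)
    return AlleleRegistry(sequences=sequences, locus_of=locus_of, founders=founders)


def simulate_genotypes(registry: AlleleRegistry, config: SimulationConfig) -> TruthSet:
    """Draw per-individual genotypes with copy-number variation.

    Each locus contributes two allele draws (with replacement, so one or two
    distinct alleles) unless dropped entirely with probability
    ``cnv_missing_prob`` — the copy-number-variation component under which
    e.g. half of individuals may lack one locus.
    """
    if not registry.sequences:
        raise ValueError("empty allele registry")
    rng = np.random.default_rng(config.seed + 1)
    genotypes: dict[str, dict[str, list[str]]] = {}
    for i in range(config.n_individuals):
        ind = f"ind{i + 1:03d}"
        g: dict[str, list[str]] = {}
        for locus in registry.founders:
            pool = registry.alleles_of_locus(locus)
            if not pool or rng.random() < config.cnv_missing_prob:
                g[locus] = []
                continue
            draws = rng.choice(pool, size=2, replace=True)
            g[locus] = sorted(set(draws.tolist()))
        genotypes[ind] = g
    return TruthSet(registry=registry, genotypes=genotypes)


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative-binomial depth draw (gamma-Poisson mixture)."""
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return int(rng.poisson(lam))


def _make_chimera(
    p1: str, p2: str, rng: np.random.Generator, forbidden: set[str]
) -> str | None:
    """Single-breakpoint recombinant of two equal-length parents, avoiding
    sequences identical to a parent or to any forbidden (true) sequence."""
    if len(p1) != len(p2):
        return None
    L = len(p1)
    for _ in range(30):
        b = int(rng.integers(1, L))
        chim = p1[:b] + p2[b:]
        if chim != p1 and chim != p2 and chim not in forbidden:
            return chim
    return None


def _make_point_error(
    parent: str, rng: np.random.Generator, forbidden: set[str]
) -> str | None:
    """Parent sequence with one substitution (80%) or one 1-nt indel (20%)."""
    for _ in range(30):
        pos = int(rng.integers(0, len(parent)))
        kind = rng.random()
        if kind < 0.8:
            new = NUCS[int(rng.integers(0, 4))]
            if new == parent[pos]:
                continue
            var = parent[:pos] + new + parent[pos + 1 :]
        elif kind < 0.9:
            var = parent[:pos] + parent[pos + 1 :]  # 1-nt deletion
        else:
            ins = NUCS[int(rng.integers(0, 4))]
            var = parent[:pos] + ins + parent[pos:]  # 1-nt insertion
        if var != parent and var not in forbidden:
            return var
    return None


def simulate_asv_table(truth: TruthSet, config: SimulationConfig) -> ASVTable:
    """Render genotypes into a read-count table with injected artefacts.

    Per amplicon the drawn total depth is partitioned among contaminant
    reads (whole-amplicon event with probability ``contamination_rate``),
    chimeric reads (binomial at ``chimera_rate`` when two or more parents
    co-amplify), point-error reads (binomial at ``error_rate``) and reads of
    the true alleles, which receive a per-allele multiplicative
    amplification bias drawn log-uniformly from
    ``allele_amplification_skew`` once per experiment (so replicates share
    the bias, as amplification efficiency is a property of the
    primer-template pair). Artefact variant counts are capped below their
    parents' counts, surplus reads being returned to the parents; counts in
    every amplicon sum exactly to the drawn depth.

    ``replicate_fraction`` of individuals receive a second, independently
    noised amplicon per primer set (tagged ``run2``). All injected artefact
    variants are appended to ``truth.artefact_class``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    registry = truth.registry
    psets = primer_sets_for(config.n_loci)
    true_seqs = set(registry.sequences.values())
    seq_to_id: dict[str, str] = {s: a for a, s in registry.sequences.items()}
    artefact_serial = 0

    skew = {
        a: float(np.exp(rng.uniform(*np.log(config.allele_amplification_skew))))
        for a in registry.sequences
    }

    individuals = list(truth.genotypes)
    n_rep = int(round(config.replicate_fraction * len(individuals)))
    replicated = set(
        rng.choice(individuals, size=min(n_rep, len(individuals)), replace=False).tolist()
    )

    columns: dict[str, dict[str, int]] = {}
    meta_rows: list[dict[str, object]] = []

    def new_variant_id() -> str:
        nonlocal artefact_serial
        artefact_serial += 1
        return f"VAR{artefact_serial:04d}"

    def variant_id_for(seq: str, label: str, parents: tuple[str, ...] = ()) -> str:
        if seq in seq_to_id:
            vid = seq_to_id[seq]
            # collision with an existing artefact of another class keeps the
            # first label; collisions with true alleles are pre-excluded
            return vid
        vid = new_variant_id()
        seq_to_id[seq] = vid
        truth.artefact_class[vid] = label
        truth.artefact_parents[vid] = parents
        return vid

    for ind in individuals:
        runs = ["run1", "run2"] if ind in replicated else ["run1"]
        for ps, loci in psets.items():
            alleles = sorted(truth.true_alleles_of(ind, loci))
            if not alleles:
                continue  # no template for this primer set: no amplification
            for run in runs:
                amp_id = f"{ind}.{ps}.{run}"
                depth = _nb_depth(rng, config.depth_mean, config.depth_dispersion)
                if depth == 0:
                    continue
                col: dict[str, int] = {}

                # --- contamination: low-level reads of a foreign true allele
                n_contam = 0
                contam_allele = None
                foreign = [
                    a
                    for locus in loci
                    for a in registry.alleles_of_locus(locus)
                    if a not in alleles
                ]
                if foreign and rng.random() < config.contamination_rate:
                    contam_allele = foreign[int(rng.integers(0, len(foreign)))]
                    n_contam = max(1, int(round(depth * rng.uniform(0.015, 0.04))))
                    n_contam = min(n_contam, depth - 1)

                d_own = depth - n_contam
                n_chim = (
                    int(rng.binomial(d_own, config.chimera_rate))
                    if len(alleles) >= 2
                    else 0
                )
                n_err = int(rng.binomial(d_own - n_chim, config.error_rate))
                n_true = d_own - n_chim - n_err

                w = np.array([skew[a] for a in alleles])
                counts = rng.multinomial(n_true, w / w.sum())
                for a, c in zip(alleles, counts):
                    col[a] = int(c)

                # --- chimeric variants: a few distinct forms per amplicon
                if n_chim > 0:
                    n_forms = int(min(n_chim, rng.integers(1, 4)))
                    per_form = rng.multinomial(n_chim, np.ones(n_forms) / n_forms)
                    for c_reads in per_form:
                        if c_reads == 0:
                            continue
                        pw = np.array([col.get(a, 0) for a in alleles], dtype=float)
                        if pw.sum() == 0 or (pw > 0).sum() < 2:
                            col[alleles[0]] = col.get(alleles[0], 0) + int(c_reads)
                            continue
                        i1, i2 = rng.choice(
                            len(alleles), size=2, replace=False, p=pw / pw.sum()
                        )
                        p1, p2 = alleles[i1], alleles[i2]
                        chim = _make_chimera(
                            registry.sequences[p1],
                            registry.sequences[p2],
                            rng,
                            true_seqs,
                        )
                        cap = min(col[p1], col[p2]) - 1
                        give_back = 0
                        c_reads = int(c_reads)
                        if chim is None or cap < 1:
                            give_back = c_reads
                            c_reads = 0
                        elif c_reads > cap:
                            give_back = c_reads - cap
                            c_reads = cap
                        if c_reads > 0 and chim is not None:
                            vid = variant_id_for(chim, "chimera", (p1, p2))
                            col[vid] = col.get(vid, 0) + c_reads
                        if give_back:
                            col[p1] = col.get(p1, 0) + give_back
                # --- point-error variants: one form per affected parent
                if n_err > 0:
                    pw = np.array([col.get(a, 0) for a in alleles], dtype=float)
                    if pw.sum() == 0:
                        col[alleles[0]] = col.get(alleles[0], 0) + n_err
                    else:
                        per_parent = rng.multinomial(n_err, pw / pw.sum())
                        for a, e_reads in zip(alleles, per_parent):
                            e_reads = int(e_reads)
                            if e_reads == 0:
                                continue
                            var = _make_point_error(
                                registry.sequences[a], rng, true_seqs
                            )
                            cap = col.get(a, 0) - 1
                            give_back = 0
                            if var is None or cap < 1:
                                give_back = e_reads
                                e_reads = 0
                            elif e_reads > cap:
                                give_back = e_reads - cap
                                e_reads = cap
                            if e_reads > 0 and var is not None:
                                vid = variant_id_for(var, "point_error", (a,))
                                col[vid] = col.get(vid, 0) + e_reads
                            if give_back:
                                col[a] = col.get(a, 0) + give_back

                if n_contam and contam_allele is not None:
                    vid = contam_allele
                    truth.artefact_class.setdefault(
                        f"{vid}@{amp_id}", "contaminant"
                    )
                    col[vid] = col.get(vid, 0) + n_contam

                columns[amp_id] = col
                meta_rows.append(
                    {
                        "amplicon": amp_id,
                        "individual": ind,
                        "primer_set": ps,
                        "run": run,
                        "replicate": run != "run1",
                    }
                )

    all_variants = sorted({v for col in columns.values() for v in col})
    counts = pd.DataFrame(
        0, index=all_variants, columns=list(columns), dtype=np.int64
    )
    for amp_id, col in columns.items():
        for vid, c in col.items():
            counts.loc[vid, amp_id] = c
    id_to_seq = {vid: s for s, vid in seq_to_id.items()}
    sequences = {vid: id_to_seq[vid] for vid in all_variants}
    amplicons = pd.DataFrame(meta_rows).set_index("amplicon")
    table = ASVTable(sequences=sequences, counts=counts, amplicons=amplicons)
    table.validate()
    return table


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[AlleleRegistry, TruthSet, ASVTable]:
    """Convenience wrapper running pool -> genotypes -> table."""
    registry = simulate_allele_pool(config)
    truth = simulate_genotypes(registry, config)
    table = simulate_asv_table(truth, config)
    return registry, truth, table


def contaminated_occurrences(truth: TruthSet) -> set[tuple[str, str]]:
    """(variant id, amplicon id) pairs injected as contamination."""
    out = set()
    for key, cls in truth.artefact_class.items():
        if cls == "contaminant" and "@" in key:
            vid, amp = key.split("@", 1)
            out.add((vid, amp))
    return out
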