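"""Allele calling from an amplicon-sequence-variant (ASV) table.

Implements the artefact-filter cascade used to separate true MHC alleles
from PCR/sequencing artefacts in deep multi-locus amplicon data:

1. discard amplicons with too few total reads;
2. discard variants whose maximum per-amplicon count across the whole
   dataset is below a floor;
3. discard off-target variants (too distant from every reference allele);
4. recompute the per-amplicon variant frequency (PAVF) on the retained
   reads and discard occurrences below a frequency floor;
5. flag single-breakpoint chimeras and single-substitution/indel error
   variants relative to higher-frequency parents in the same amplicon;
6. flag low-frequency occurrences of variants that are confidently called
   in other amplicons (cross-sample contamination);
7. mark amplicons retaining more variants than the primer set can
   plausibly yield as "unclear".

Every variant occurrence ends exactly once: called, or rejected with a
reason code. Replicated amplicons are compared set-wise to estimate
genotyping repeatability.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import common_prefix_len, common_suffix_len, edit_distance, p_distance
from .simulate import ASVTable

REASONS = (
    "low_count",
    "off_target",
    "low_pavf",
    "chimera",
    "point_artefact",
    "cross_amplicon",
    "over_cap",
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filter cascade.

    ``min_reads_per_amplicon`` and ``min_variant_max_count`` are exclusive
    floors ("less than" is rejected). ``max_expected_alleles`` caps the
    number of surviving variants per amplicon: an int applies everywhere, a
    mapping is keyed by primer-set id (a two-locus primer set can yield at
    most 4 alleles, a one-locus set at most 2); ``None`` disables the cap.
    """

    min_reads_per_amplicon: int = 100
    min_variant_max_count: int = 10
    min_pavf: float = 0.01
    offtarget_max_distance: float = 0.40
    parent_child_ratio: float = 1 / 3
    cross_amplicon_low: float = 0.05
    max_expected_alleles: int | Mapping[str, int] | None = None

    def validate(self) -> None:
        if not 0 < self.min_pavf < 1:
            raise ValueError("min_pavf must be in (0, 1)")
        if not 0 < self.parent_child_ratio <= 1:
            raise ValueError("parent_child_ratio must be in (0, 1]")

    def cap_for(self, primer_set: str) -> int | None:
        if self.max_expected_alleles is None:
            return None
        if isinstance(self.max_expected_alleles, int):
            return self.max_expected_alleles
        return self.max_expected_alleles.get(primer_set)


@dataclass
class GenotypeCall:
    """Outcome for one amplicon: called alleles plus a full rejection audit."""

    amplicon: str
    individual: str
    primer_set: str
    called: list[str] = field(default_factory=list)
    rejected: dict[str, str] = field(default_factory=dict)
    status: str = "ok"  # ok | discarded_low_coverage | unclear

    def __post_init__(self) -> None:
        overlap = set(self.called) & set(self.rejected)
        if overlap:
            raise ValueError(f"variants both called and rejected: {overlap}")


@dataclass
class ReplicateReport:
    pairs_compared: int
    identical: int
    diffs: list[dict[str, object]] = field(default_factory=list)

    @property
    def concordance(self) -> float:
        return self.identical / self.pairs_compared if self.pairs_compared else float("nan")


def compute_pavf(table: ASVTable) -> pd.DataFrame:
    """Per-amplicon variant frequency: count / amplicon total.

    Amplicons with zero total reads are excluded from the result (their
    frequencies are undefined); retained columns sum to 1.
    """
    totals = table.counts.sum(axis=0)
    keep = totals > 0
    return table.counts.loc[:, keep] / totals[keep]


def _survivor_pavf(counts: pd.DataFrame) -> pd.DataFrame:
    totals = counts.sum(axis=0)
    totals = totals.replace(0, np.nan)
    return counts / totals


def detect_chimeras(
    sequences: Mapping[str, str], pavf: Mapping[str, float]
) -> set[str]:
    """Flag variants explainable as a single-breakpoint concatenation of two
    distinct higher-frequency variants of the same amplicon.

    A variant v is flagged iff parents p1 != p2 exist, both with strictly
    higher PAVF, such that v = p1[:b] + p2[b:] for some internal breakpoint
    after (trivial, equal-length) alignment; v identical to a parent is
    never flagged. Parents with indels relative to v are not scanned — in
    this amplicon system co-amplified alleles are length-matched.
    """
    flagged: set[str] = set()
    ids = sorted(sequences, key=lambda v: pavf[v])
    for v in ids:
        sv = sequences[v]
        parents = [p for p in ids if pavf[p] > pavf[v] and sequences[p] != sv]
        for p1, p2 in itertools.permutations(parents, 2):
            s1, s2 = sequences[p1], sequences[p2]
            if len(s1) != len(sv) or len(s2) != len(sv):
                continue
            if common_prefix_len(sv, s1) + common_suffix_len(sv, s2) >= len(sv):
                flagged.add(v)
                break
    return flagged


def detect_point_artefacts(
    sequences: Mapping[str, str],
    pavf: Mapping[str, float],
    cfg: FilterConfig,
) -> set[str]:
    """Flag variants within edit distance 1 (one substitution or one 1-nt
    indel) of a same-amplicon parent whose frequency exceeds the variant's
    by at least 1/parent_child_ratio.

    Two co-dominant alleles one substitution apart (near 1:1 frequencies)
    fail the ratio test and are both retained.
    """
    flagged: set[str] = set()
    ids = list(sequences)
    for v in ids:
        for p in ids:
            if p == v:
                continue
            if pavf[v] > cfg.parent_child_ratio * pavf[p]:
                continue
            if 0 <= edit_distance(sequences[v], sequences[p], k=1) <= 1:
                flagged.add(v)
                break
    return flagged


def cross_amplicon_screen(
    survivors: Mapping[str, set[str]],
    pavf: pd.DataFrame,
    cfg: FilterConfig,
    replicate_groups: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, set[str]]:
    """Flag low-frequency occurrences of variants confidently called
    elsewhere (the cross-sample contamination screen).

    Variant v in amplicon a is flagged iff PAVF(v, a) < cross_amplicon_low
    and v survives at PAVF >= cross_amplicon_low in at least one other
    amplicon. When replicates of a exist and none of them retains v the
    flag is confirmed; otherwise it stands as putative. Both cases carry
    reason ``cross_amplicon``.
    """
    strong_holders: dict[str, set[str]] = {}
    for amp, vs in survivors.items():
        for v in vs:
            if pavf.at[v, amp] >= cfg.cross_amplicon_low:
                strong_holders.setdefault(v, set()).add(amp)

    flags: dict[str, set[str]] = {amp: set() for amp in survivors}
    for amp, vs in survivors.items():
        for v in vs:
            if pavf.at[v, amp] >= cfg.cross_amplicon_low:
                continue
            holders = strong_holders.get(v, set()) - {amp}
            if holders:
                flags[amp].add(v)
    # replicate confirmation does not change the flag set, only its
    # confidence; callers wanting the distinction can recompute it from
    # replicate_groups
    _ = replicate_groups
    return flags


def filter_cascade(
    table: ASVTable,
    references: Mapping[str, str] | Sequence[str],
    cfg: FilterConfig | None = None,
) -> list[GenotypeCall]:
    """Run the full artefact-filter cascade and return one call per amplicon.

    ``references`` are known on-target allele sequences (e.g. the per-locus
    genomic references) used only for the off-target screen.
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    table.validate()
    if isinstance(references, Mapping):
        refs = list(references.values())
    else:
        refs = list(references)
    if not refs:
        raise ValueError("reference panel is empty")
    if table.counts.empty:
        raise ValueError("empty ASV table")

    counts = table.counts
    meta = table.amplicons
    calls: dict[str, GenotypeCall] = {}
    for amp in counts.columns:
        calls[amp] = GenotypeCall(
            amplicon=amp,
            individual=str(meta.at[amp, "individual"]),
            primer_set=str(meta.at[amp, "primer_set"]),
        )

    present: dict[str, set[str]] = {
        amp: set(counts.index[counts[amp] > 0]) for amp in counts.columns
    }

    # (1) amplicon coverage floor
    totals = counts.sum(axis=0)
    low_cov = [amp for amp in counts.columns if totals[amp] < cfg.min_reads_per_amplicon]
    for amp in low_cov:
        calls[amp].status = "discarded_low_coverage"
    live_amps = [a for a in counts.columns if a not in set(low_cov)]
    sub = counts.loc[:, live_amps]

    # (2) dataset-wide variant count floor
    max_per_variant = sub.max(axis=1) if live_amps else pd.Series(dtype=np.int64)
    low_count = set(sub.index[(max_per_variant < cfg.min_variant_max_count)])

    # (3) off-target screen against the reference panel
    off_target: set[str] = set()
    for v in sub.index:
        if v in low_count:
            continue
        dmin = min(p_distance(table.sequences[v], r) for r in refs)
        if dmin > cfg.offtarget_max_distance:
            off_target.add(v)

    retained = [v for v in sub.index if v not in low_count and v not in off_target]
    for amp in live_amps:
        for v in present[amp]:
            if v in low_count:
                calls[amp].rejected[v] = "low_count"
            elif v in off_target:
                calls[amp].rejected[v] = "off_target"

    # (4) PAVF on the reduced table; per-occurrence frequency floor
    reduced = sub.loc[retained]
    pavf = _survivor_pavf(reduced)
    survivors: dict[str, set[str]] = {}
    for amp in live_amps:
        keep: set[str] = set()
        for v in retained:
            if reduced.at[v, amp] <= 0:
                continue
            if pavf.at[v, amp] < cfg.min_pavf:
                calls[amp].rejected[v] = "low_pavf"
            else:
                keep.add(v)
        survivors[amp] = keep

    # (5) within-amplicon artefact structure: chimeras, then point errors
    for amp in live_amps:
        vs = survivors[amp]
        if len(vs) >= 3:
            local_pavf = {v: float(pavf.at[v, amp]) for v in vs}
            local_seqs = {v: table.sequences[v] for v in vs}
            chims = detect_chimeras(local_seqs, local_pavf)
            for v in chims:
                calls[amp].rejected[v] = "chimera"
            vs -= chims
        if len(vs) >= 2:
            local_pavf = {v: float(pavf.at[v, amp]) for v in vs}
            local_seqs = {v: table.sequences[v] for v in vs}
            points = detect_point_artefacts(local_seqs, local_pavf, cfg)
            for v in points:
                calls[amp].rejected[v] = "point_artefact"
            vs -= points

    # (6) cross-amplicon (contamination) screen
    flags = cross_amplicon_screen(survivors, pavf, cfg)
    for amp, vs in flags.items():
        for v in vs:
            calls[amp].rejected[v] = "cross_amplicon"
        survivors[amp] -= vs

    # (7) plausibility cap per primer set
    for amp in live_amps:
        calls[amp].called = sorted(survivors[amp])
        cap = cfg.cap_for(calls[amp].primer_set)
        if cap is not None and len(survivors[amp]) > cap:
            calls[amp].status = "unclear"

    # audit completeness: every occurrence called or rejected
    for amp in live_amps:
        accounted = set(calls[amp].called) | set(calls[amp].rejected)
        missing = present[amp] - accounted
        if missing:  # pragma: no cover - defensive
            raise AssertionError(f"unaudited variants in {amp}: {missing}")
    return list(calls.values())


def replicate_concordance(calls: Sequence[GenotypeCall]) -> ReplicateReport:
    """Compare genotypes between replicate amplicons of the same individual
    and primer set (all unordered pairs; n replicates give n(n-1)/2
    comparisons). Amplicons discarded for low coverage are not compared.
    """
    groups: dict[tuple[str, str], list[GenotypeCall]] = {}
    for c in calls:
        if c.status == "discarded_low_coverage":
            continue
        groups.setdefault((c.individual, c.primer_set), []).append(c)

    pairs = identical = 0
    diffs: list[dict[str, object]] = []
    for (ind, ps), group in sorted(groups.items()):
        for a, b in itertools.combinations(group, 2):
            pairs += 1
            if set(a.called) == set(b.called):
                identical += 1
            else:
                diffs.append(
                    {
                        "individual": ind,
                        "primer_set": ps,
                        "amplicon_a": a.amplicon,
                        "amplicon_b": b.amplicon,
                        "only_a": sorted(set(a.called) - set(b.called)),
                        "only_b": sorted(set(b.called) - set(a.called)),
                    }
                )
    return ReplicateReport(pairs_compared=pairs, identical=identical, diffs=diffs)


def genotyping_accuracy(calls: Sequence[GenotypeCall], truth, primer_sets) -> dict[str, float]:
    """Micro-averaged allele precision/recall of calls against a TruthSet.

    Truth for an amplicon is the individual's genotype restricted to the
    loci of its primer set; every amplicon (including discarded ones, which
    contribute empty call sets) is scored.
    """
    tp = fp = fn = 0
    for c in calls:
        expected = truth.true_alleles_of(c.individual, primer_sets[c.primer_set])
        got = set(c.called)
        tp += len(got & expected)
        fp += len(got - expected)
        fn += len(expected - got)
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return {"precision": precision, "recall": recall, "tp": tp, "fp": fp, "fn": fn}
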