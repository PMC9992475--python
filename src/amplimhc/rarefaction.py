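"""Allele accumulation (rarefaction) curves by permutation.

For each sample size n, individuals are drawn without replacement and the
distinct alleles in the subsample counted; repeating the draw gives the
mean and SD of the discovery curve. The exact expectation has a closed
hypergeometric form used as an independent check: for an allele carried by
c of N individuals, P(detected in a sample of n) = 1 - C(N-c, n)/C(N, n).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def allele_accumulation(
    genotypes: Mapping[str, set[str] | Sequence[str]],
    reps: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation accumulation curve over all individuals.

    ``genotypes`` maps individual -> alleles carried. Returns a DataFrame
    with columns ``n``, ``mean``, ``sd`` for n = 1..N.
    """
    if not genotypes:
        raise ValueError("no genotyped individuals")
    inds = sorted(genotypes)
    allele_sets = [frozenset(genotypes[i]) for i in inds]
    N = len(inds)
    rng = np.random.default_rng(seed)
    rows = []
    for n in range(1, N + 1):
        counts = np.empty(reps, dtype=np.int64)
        for r in range(reps):
            idx = rng.choice(N, size=n, replace=False)
            counts[r] = len(frozenset().union(*(allele_sets[i] for i in idx)))
        rows.append({"n": n, "mean": counts.mean(), "sd": counts.std(ddof=0)})
    return pd.DataFrame(rows)


def expected_accumulation(
    genotypes: Mapping[str, set[str] | Sequence[str]]
) -> pd.DataFrame:
    """Closed-form expected curve: E[distinct alleles at n] =
    sum over alleles a of 1 - C(N - c_a, n) / C(N, n)."""
    inds = sorted(genotypes)
    N = len(inds)
    carriers: dict[str, int] = {}
    for i in inds:
        for a in set(genotypes[i]):
            carriers[a] = carriers.get(a, 0) + 1
    rows = []
    for n in range(1, N + 1):
        e = sum(1 - comb(N - c, n) / comb(N, n) for c in carriers.values())
        rows.append({"n": n, "expected": e})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortCurves:
    curves: dict[str, pd.DataFrame]


def accumulation_by_cohort(
    genotypes_by_primer_set: Mapping[str, Mapping[str, set[str]]],
    reps: int = 500,
    seed: int = 0,
) -> CohortCurves:
    """Curves per primer set plus the intersection cohort (individuals
    genotyped with every primer set, pooling their alleles)."""
    curves: dict[str, pd.DataFrame] = {}
    for k, (ps, geno) in enumerate(sorted(genotypes_by_primer_set.items())):
        if geno:
            curves[ps] = allele_accumulation(geno, reps=reps, seed=seed + k)
    sets = [set(g) for g in genotypes_by_primer_set.values()]
    common = set.intersection(*sets) if sets else set()
    pooled = {
        ind: set().union(
            *(genotypes_by_primer_set[ps][ind] for ps in genotypes_by_primer_set)
        )
        for ind in common
    }
    if pooled:
        curves["all"] = allele_accumulation(pooled, reps=reps, seed=seed + 99)
    return CohortCurves(curves=curves)
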