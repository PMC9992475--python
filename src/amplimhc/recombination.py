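"""Recombination signal in allele alignments.

Two complementary detectors:

* the four-gamete (Hudson–Kaplan) lower bound Rm on the number of
  historical recombination events, from incompatible pairs of biallelic
  sites reduced to a minimal set of non-overlapping intervals;
* the pairwise homoplasy index (Phi) permutation test, which asks whether
  nearby sites are more compatible than expected if incompatibility were
  independent of genomic position (the signature of recombination).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._seq import seqs_to_array

_MISSING = {"-", ".", "N", "n"}


def _site_matrix(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """(character matrix, alignment positions) of columns without missing
    data; positions are 0-based alignment coordinates."""
    arr = seqs_to_array([s.upper() for s in seqs])
    ok = ~np.isin(arr, list(_MISSING)).any(axis=0)
    return arr[:, ok], np.flatnonzero(ok)


def biallelic_segregating(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Binary matrix (individuals x sites) of gap-free biallelic
    segregating sites plus their alignment positions (0-based)."""
    arr, pos = _site_matrix(seqs)
    cols = []
    kept = []
    for c in range(arr.shape[1]):
        states = sorted(set(arr[:, c]))
        if len(states) == 2:
            cols.append((arr[:, c] == states[1]).astype(np.int8))
            kept.append(pos[c])
    if not cols:
        return np.zeros((len(seqs), 0), dtype=np.int8), np.array([], dtype=int)
    return np.column_stack(cols), np.array(kept)


def incompatible_pairs(binary: np.ndarray) -> list[tuple[int, int]]:
    """Site-index pairs (i < j) showing all four gametes 00/01/10/11."""
    out = []
    m = binary.shape[1]
    for i, j in itertools.combinations(range(m), 2):
        g = {(int(a), int(b)) for a, b in zip(binary[:, i], binary[:, j])}
        if len(g) == 4:
            out.append((i, j))
    return out


@dataclass(frozen=True)
class RmResult:
    rm: int
    intervals: list[tuple[int, int]]  # alignment positions of reduced intervals


def four_gamete_rm(seqs: Sequence[str]) -> RmResult:
    """Hudson–Kaplan minimum number of recombination events.

    Incompatible site pairs define open intervals that must each contain at
    least one recombination breakpoint; Rm is the minimum number of
    breakpoints hitting every interval (greedy stabbing of intervals sorted
    by right endpoint, which is optimal for intervals). Sites with gaps or
    more than two alleles are excluded from the scan.
    """
    binary, pos = biallelic_segregating(seqs)
    if binary.shape[1] < 2:
        return RmResult(rm=0, intervals=[])
    pairs = incompatible_pairs(binary)
    if not pairs:
        return RmResult(rm=0, intervals=[])
    # greedy minimum point cover; chosen breakpoints sit just left of the
    # interval's right endpoint (between sites r-1 and r)
    pairs.sort(key=lambda ij: ij[1])
    rm = 0
    last = -1
    chosen: list[tuple[int, int]] = []
    for left, right in pairs:
        if last < left:
            rm += 1
            last = right - 1
            chosen.append((int(pos[right - 1]), int(pos[right])))
    return RmResult(rm=rm, intervals=chosen)


@dataclass(frozen=True)
class PhiResult:
    statistic: float
    p_value: float
    n_informative: int
    computable: bool
    reason: str = ""


def _informative_sites(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Parsimony-informative columns (>=2 states each seen >=2 times),
    missing characters treated as absent observations."""
    arr = seqs_to_array([s.upper() for s in seqs])
    cols = []
    kept = []
    for c in range(arr.shape[1]):
        col = arr[:, c]
        obs = col[~np.isin(col, list(_MISSING))]
        vals, counts = np.unique(obs, return_counts=True)
        if (counts >= 2).sum() >= 2:
            cols.append(c)
            kept.append(c)
    return arr[:, cols], np.array(kept)


def _refined_incompatibility(col_i: np.ndarray, col_j: np.ndarray) -> int:
    """Minimum number of extra (homoplasious) mutations forced by the joint
    pattern of two sites: cycles of the bipartite state graph, e - v + c."""
    ok = ~(np.isin(col_i, list(_MISSING)) | np.isin(col_j, list(_MISSING)))
    a, b = col_i[ok], col_j[ok]
    edges = set(zip(a.tolist(), b.tolist()))
    if not edges:
        return 0
    left = {x for x, _ in edges}
    right = {y for _, y in edges}
    # connected components via union-find over states
    parent: dict[object, object] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for x, y in edges:
        union(("L", x), ("R", y))
    roots = {find(("L", x)) for x in left} | {find(("R", y)) for y in right}
    e, v, c = len(edges), len(left) + len(right), len(roots)
    return e - v + c


def phi_test(
    seqs: Sequence[str],
    window: int = 100,
    permutations: int = 1000,
    seed: int = 0,
) -> PhiResult:
    """Pairwise homoplasy index permutation test of recombination.

    The statistic is the mean refined incompatibility over pairs of
    parsimony-informative sites whose alignment positions are at most
    ``window`` nucleotides apart; the p-value is the fraction of random
    site-order permutations with a statistic at most the observed one
    (with the +1 small-sample correction). Low observed incompatibility
    among *nearby* sites relative to permutation is the recombination
    signature.
    """
    cols, kept = _informative_sites(seqs)
    m = cols.shape[1]
    if m < 3:
        return PhiResult(
            statistic=float("nan"),
            p_value=float("nan"),
            n_informative=m,
            computable=False,
            reason="fewer than 3 parsimony-informative sites",
        )
    scores = np.zeros((m, m))
    for i, j in itertools.combinations(range(m), 2):
        s = _refined_incompatibility(cols[:, i], cols[:, j])
        scores[i, j] = scores[j, i] = s
    # position-pairs within the window are fixed; permutation shuffles which
    # informative site occupies which position
    A, B = [], []
    for a, b in itertools.combinations(range(m), 2):
        if abs(int(kept[a]) - int(kept[b])) <= window:
            A.append(a)
            B.append(b)
    if not A:
        return PhiResult(
            statistic=float("nan"),
            p_value=float("nan"),
            n_informative=m,
            computable=False,
            reason="no informative site pairs within the window",
        )
    A = np.array(A)
    B = np.array(B)
    observed = float(scores[A, B].mean())
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(m)
        if scores[perm[A], perm[B]].mean() <= observed:
            hits += 1
    p = (1 + hits) / (1 + permutations)
    return PhiResult(
        statistic=observed, p_value=float(p), n_informative=m, computable=True
    )
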