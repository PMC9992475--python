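"""Sequence diversity statistics for allele alignments.

Conventions follow the classic population-genetics tools: nucleotide
statistics (segregating sites S, mean pairwise differences k, nucleotide
diversity π) use *complete deletion* of gap-containing columns, so all
pairs are compared on the same site set; amino-acid p-distances use
*pairwise deletion* of gapped residues. With three-locus exon-2 data the
complete-deletion convention makes the combined analysis use the columns
shared by deletion-bearing and deletion-free alleles.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._seq import CODON_TABLE, seqs_to_array, ungapped_columns

GAPS = ("-", ".")


@dataclass(frozen=True)
class DiversitySummary:
    n_alleles: int
    n_sites: int
    S: int
    k: float
    pi: float
    pi_sd: float  # Nei (1987) eq. 10.7 total variance, as SD
    aa_distance: float
    aa_distance_se: float


def _check_alignment(seqs: Sequence[str]) -> None:
    if len(seqs) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("alignment rows have unequal lengths")


def _complete_deletion(seqs: Sequence[str]) -> np.ndarray:
    arr = seqs_to_array([s.upper() for s in seqs])
    keep = ungapped_columns(seqs)
    if not keep.any():
        raise ValueError("all alignment columns contain gaps")
    return arr[:, keep]


def segregating_sites(seqs: Sequence[str]) -> tuple[int, int]:
    """(S, sites analysed): polymorphic count among gap-free columns."""
    _check_alignment(seqs)
    arr = _complete_deletion(seqs)
    s = int(sum(len(set(col)) > 1 for col in arr.T))
    return s, arr.shape[1]


def pairwise_diff_stats(seqs: Sequence[str]) -> tuple[float, float, float]:
    """(k, π, SD of π) over all unordered pairs, complete deletion.

    k is the mean per-pair count of differing sites, π = k / sites. The SD
    is the square root of Nei's (1987, eq. 10.7) total variance of π,
    combining sampling and stochastic components.
    """
    _check_alignment(seqs)
    arr = _complete_deletion(seqs)
    n, L = arr.shape
    diffs = [
        int((arr[i] != arr[j]).sum()) for i, j in itertools.combinations(range(n), 2)
    ]
    k = float(np.mean(diffs))
    pi = k / L
    var = (n + 1) / (3 * (n - 1) * L) * pi + (
        2 * (n**2 + n + 3) / (9 * n * (n - 1))
    ) * pi**2
    return k, pi, float(np.sqrt(var))


def infer_frame(reference: str) -> int:
    """Reading frame (0/1/2) in which the reference translates without
    internal stops; raises if none does."""
    ref = reference.replace("-", "").replace(".", "")
    for frame in range(3):
        aa = _translate_frame(ref, frame)
        if "*" not in aa:
            return frame
    raise ValueError("no stop-free reading frame in reference")


def _translate_frame(seq: str, frame: int) -> str:
    s = seq[frame:]
    return "".join(
        CODON_TABLE.get(s[i : i + 3], "X") for i in range(0, len(s) - len(s) % 3, 3)
    )


def translate_alignment(seqs: Sequence[str], frame: int = 0) -> list[str]:
    """Codon-wise translation of an in-frame nucleotide alignment.

    Codons containing a gap character translate to '-', codons with
    non-ACGT bases to 'X'. Requires gaps to respect codon boundaries
    (true of codon-aware alignments).
    """
    if len(seqs) > 1 and len({len(s) for s in seqs}) != 1:
        raise ValueError("alignment rows have unequal lengths")
    out = []
    for s in seqs:
        s = s.upper()[frame:]
        aa = []
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i : i + 3]
            if any(c in GAPS for c in codon):
                aa.append("-")
            else:
                aa.append(CODON_TABLE.get(codon, "X"))
        out.append("".join(aa))
    return out


def aa_p_distance_matrix(
    seqs: Sequence[str], frame: int = 0, ids: Sequence[str] | None = None
) -> tuple[np.ndarray, list[int]]:
    """Pairwise amino-acid p-distance matrix with pairwise deletion.

    Alleles translating with an internal stop codon are excluded (a warning
    names them; functional MHC alleles are expected stop-free) and their
    row indices returned.
    """
    prots = translate_alignment(seqs, frame)
    excluded = [i for i, p in enumerate(prots) if "*" in p]
    if excluded:
        names = [ids[i] if ids else str(i) for i in excluded]
        warnings.warn(f"alleles with stop codons excluded from AA distances: {names}")
    n = len(prots)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 0.0)
    keep = [i for i in range(n) if i not in excluded]
    for i, j in itertools.combinations(keep, 2):
        a, b = prots[i], prots[j]
        compared = diff = 0
        for x, y in zip(a, b):
            if x in GAPS or y in GAPS or x == "X" or y == "X":
                continue
            compared += 1
            if x != y:
                diff += 1
        d = diff / compared if compared else np.nan
        mat[i, j] = mat[j, i] = d
    return mat, excluded


def group_mean_distances(
    mat: np.ndarray, labels: Sequence[str]
) -> dict[tuple[str, str], float]:
    """Mean within-group (label, label) and between-group (a, b) distances
    from a pairwise matrix."""
    labels = list(labels)
    groups = sorted(set(labels))
    out: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations_with_replacement(groups, 2):
        ia = [i for i, l in enumerate(labels) if l == a]
        ib = [i for i, l in enumerate(labels) if l == b]
        if a == b:
            vals = [mat[i, j] for i, j in itertools.combinations(ia, 2)]
        else:
            vals = [mat[i, j] for i in ia for j in ib]
        vals = [v for v in vals if np.isfinite(v)]
        out[(a, b)] = float(np.mean(vals)) if vals else float("nan")
    return out


def diversity_summary(
    seqs: Sequence[str],
    frame: int = 0,
    ids: Sequence[str] | None = None,
    bootstrap_se_reps: int = 200,
    seed: int = 0,
) -> DiversitySummary:
    """Per-alignment bundle: S, k, π (±SD) and mean AA p-distance (±SE).

    The AA-distance SE is a bootstrap over residue columns.
    """
    s, sites = segregating_sites(seqs)
    k, pi, pi_sd = pairwise_diff_stats(seqs)
    mat, _ = aa_p_distance_matrix(seqs, frame, ids)
    iu = np.triu_indices_from(mat, k=1)
    vals = mat[iu]
    vals = vals[np.isfinite(vals)]
    aa_mean = float(np.mean(vals)) if len(vals) else float("nan")
    aa_se = _aa_bootstrap_se(seqs, frame, bootstrap_se_reps, seed)
    return DiversitySummary(
        n_alleles=len(seqs),
        n_sites=sites,
        S=s,
        k=k,
        pi=pi,
        pi_sd=pi_sd,
        aa_distance=aa_mean,
        aa_distance_se=aa_se,
    )


def _aa_bootstrap_se(
    seqs: Sequence[str], frame: int, reps: int, seed: int
) -> float:
    if reps <= 0:
        return float("nan")
    prots = translate_alignment(seqs, frame)
    prots = [p for p in prots if "*" not in p]
    if len(prots) < 2:
        return float("nan")
    arr = seqs_to_array(prots)
    n, L = arr.shape
    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(range(n), 2))
    means = []
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        sub = arr[:, cols]
        vals = []
        for i, j in pairs:
            a, b = sub[i], sub[j]
            ok = ~(np.isin(a, GAPS) | np.isin(b, GAPS) | (a == "X") | (b == "X"))
            if ok.sum():
                vals.append((a[ok] != b[ok]).mean())
        if vals:
            means.append(np.mean(vals))
    return float(np.std(means, ddof=1)) if len(means) > 1 else float("nan")
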