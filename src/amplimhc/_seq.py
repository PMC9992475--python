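"""Low-level nucleotide/codon helpers shared across modules.

Sequences are plain upper-case strings over ACGT (alignments may add '-').
Codon-level work always assumes reading frame 0 unless a frame offset is
passed explicitly.
"""

from __future__ import annotations

from typing import Iterable

import edlib
import numpy as np

NUCS = "ACGT"

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Standard genetic code (DNA codons -> one-letter amino acids, '*' = stop).
_BASES = ("T", "C", "A", "G")
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE: dict[str, str] = {
    a + b + c: _AAS[i * 16 + j * 4 + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def translate(seq: str, frame: int = 0) -> str:
    """Translate a gap-free nucleotide string; trailing partial codon dropped."""
    s = seq[frame:]
    return "".join(
        CODON_TABLE.get(s[i : i + 3], "X") for i in range(0, len(s) - len(s) % 3, 3)
    )


def has_internal_stop(seq: str, frame: int = 0) -> bool:
    aa = translate(seq, frame)
    return "*" in aa[:-1] or (len(aa) > 0 and aa[-1] == "*")


def random_coding_sequence(n_codons: int, rng: np.random.Generator) -> str:
    """Random in-frame coding sequence with no stop codons."""
    codons = [c for c in CODON_TABLE if c not in STOP_CODONS]
    idx = rng.integers(0, len(codons), size=n_codons)
    return "".join(codons[i] for i in idx)


def mutate_avoiding_stops(
    seq: str, n_subs: int, rng: np.random.Generator, max_tries: int = 200
) -> str:
    """Apply ``n_subs`` substitutions at distinct positions, keeping frame-0
    translation free of stop codons (rejection sampling per site)."""
    s = list(seq)
    if n_subs == 0:
        return seq
    positions = rng.choice(len(s), size=min(n_subs, len(s)), replace=False)
    for pos in positions:
        old = s[pos]
        for _ in range(max_tries):
            new = NUCS[rng.integers(0, 4)]
            if new == old:
                continue
            codon_start = (pos // 3) * 3
            codon = s[codon_start] if codon_start != pos else new
            trial = s[codon_start : codon_start + 3]
            trial[pos - codon_start] = new
            if "".join(trial) not in STOP_CODONS:
                s[pos] = new
                break
    return "".join(s)


def p_distance(a: str, b: str) -> float:
    """Uncorrected distance between two unaligned sequences.

    Global (Needleman-Wunsch) edit distance via edlib divided by the longer
    length; a cheap screen adequate for off-target and nearest-reference
    queries where sequences are either near-identical or very different.
    """
    if not a or not b:
        return 1.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return d / max(len(a), len(b))


def aligned_p_distance(a: str, b: str) -> float:
    """p-distance from a global alignment with pairwise deletion of
    gap (indel) columns: mismatches / aligned match+mismatch columns."""
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    qa, ta = nice["query_aligned"], nice["target_aligned"]
    compared = mismatch = 0
    for x, y in zip(qa, ta):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x != y:
            mismatch += 1
    return mismatch / compared if compared else 1.0


def edit_distance(a: str, b: str, k: int = -1) -> int:
    """Levenshtein distance (edlib); ``k`` caps the search (-1 = unbounded;
    returns -1 when the distance exceeds ``k``)."""
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]


def common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def common_suffix_len(a: str, b: str) -> int:
    return common_prefix_len(a[::-1], b[::-1])


def ungapped_columns(seqs: Iterable[str]) -> np.ndarray:
    """Boolean mask of alignment columns containing no gap in any sequence."""
    arr = np.array([list(s) for s in seqs])
    return ~np.any((arr == "-") | (arr == "."), axis=0)


def seqs_to_array(seqs: Iterable[str]) -> np.ndarray:
    return np.array([list(s) for s in seqs])
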