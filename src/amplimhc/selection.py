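"""Tests of positive selection on codon alignments (Nei–Gojobori 1986).

The classical counting approach: each codon carries fractional synonymous
and nonsynonymous site counts (summing to 3, with mutations to stop codons
excluded from consideration); differences between a codon pair are averaged
over all minimal substitution pathways that avoid stop codons. Observed
proportions pS = Sd/S and pN = Nd/N are corrected for multiple hits with
Jukes–Cantor, d = -(3/4)·ln(1 - 4p/3). Selection on a codon partition
(e.g. the peptide-binding sites of an MHC exon) is assessed with a
one-tailed Z-test of dN > dS whose variances come from bootstrap resampling
of codon columns.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.stats import norm

from ._seq import CODON_TABLE, NUCS, STOP_CODONS

#: Default peptide-binding-site mask (1-based codon indices on the amplicon).
#: Human HLA-DRβ1 peptide-contact residues (the classic crystallographic
#: contact set) mapped onto the exon-2 amplicon assuming amplicon codon 1
#: corresponds to β1 residue 5; see docs/methods.md for the mapping.
DEFAULT_PBS_RESOURCE = "pbs_mask_default.txt"


@dataclass(frozen=True)
class SelectionSummary:
    partition: str
    n_codons: int
    dN: float
    dN_se: float
    dS: float
    dS_se: float
    dn_ds: float
    z: float
    p_value: float


class SaturationError(ValueError):
    """Observed proportion >= 3/4: Jukes–Cantor correction undefined."""


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    Each position contributes one site, split by the fraction of synonymous
    changes among the changes that do not create a stop codon; the two
    fractions therefore sum to 3 for any sense codon.
    """
    if codon in STOP_CODONS or any(c not in NUCS for c in codon):
        raise ValueError(f"invalid codon {codon!r}")
    aa = CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        s = valid = 0
        for nuc in NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if CODON_TABLE[alt] == aa:
                s += 1
        syn += s / valid if valid else 0.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_diff_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over all minimal substitution pathways that avoid stop codons.

    If every pathway passes through a stop codon (possible for some distant
    pairs), pathways are averaged without the stop constraint.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = _pathways(c1, c2, diff_pos, avoid_stops=True)
    if not results:
        results = _pathways(c1, c2, diff_pos, avoid_stops=False)
    syn = sum(r[0] for r in results) / len(results)
    return syn, len(diff_pos) - syn


def _pathways(c1: str, c2: str, diff_pos: list[int], avoid_stops: bool):
    out = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if avoid_stops and nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                syn += 1
            cur = nxt
        if ok:
            out.append((syn,))
    return out


def jukes_cantor(p: float) -> float:
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise SaturationError(f"p = {p:.4f} >= 3/4; distance undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _usable(codon: str) -> bool:
    return (
        len(codon) == 3
        and all(c in NUCS for c in codon)
        and codon not in STOP_CODONS
    )


def ng86_pair(codons1: Sequence[str], codons2: Sequence[str]) -> tuple[float, float]:
    """Jukes–Cantor-corrected (dN, dS) between two codon sequences.

    Codons with gaps, ambiguous bases or stop codons in either sequence are
    dropped pairwise. Raises :class:`SaturationError` when either observed
    proportion reaches 3/4.
    """
    if len(codons1) != len(codons2):
        raise ValueError("codon sequences differ in length")
    S = N = Sd = Nd = 0.0
    for a, b in zip(codons1, codons2):
        if not (_usable(a) and _usable(b)):
            continue
        sa, na = codon_site_counts(a)
        sb, nb = codon_site_counts(b)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = codon_diff_counts(a, b)
        Sd += sd
        Nd += nd
    if S == 0 or N == 0:
        raise ValueError("no comparable codons")
    return jukes_cantor(Nd / N), jukes_cantor(Sd / S)


def to_codons(seq: str, frame: int = 0) -> list[str]:
    s = seq.upper()[frame:]
    return [s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3)]


def load_pbs_mask(path=None) -> list[int]:
    """1-based codon indices of the peptide-binding sites.

    ``path=None`` loads the packaged default mask; a file lists one index
    per line ('#' comments allowed). Indices beyond the alignment are
    ignored at use time so one mask serves amplicons of slightly different
    spans.
    """
    if path is None:
        text = (
            resources.files("amplimhc").joinpath(f"data/{DEFAULT_PBS_RESOURCE}").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    out = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(int(line))
    if any(i < 1 for i in out):
        raise ValueError("PBS mask indices are 1-based and must be >= 1")
    return sorted(set(out))


def _pair_codon_tables(
    codon_rows: list[list[str]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per (pair, codon) arrays of syn sites, nonsyn sites, syn diffs,
    nonsyn diffs (NaN where a codon is dropped pairwise). These additive
    components make partition restriction and codon bootstrap cheap."""
    n = len(codon_rows)
    L = len(codon_rows[0])
    pairs = list(itertools.combinations(range(n), 2))
    S = np.full((len(pairs), L), np.nan)
    N = np.full((len(pairs), L), np.nan)
    Sd = np.full((len(pairs), L), np.nan)
    Nd = np.full((len(pairs), L), np.nan)
    for pi, (i, j) in enumerate(pairs):
        for c in range(L):
            a, b = codon_rows[i][c], codon_rows[j][c]
            if not (_usable(a) and _usable(b)):
                continue
            sa, na = codon_site_counts(a)
            sb, nb = codon_site_counts(b)
            sd, nd = codon_diff_counts(a, b)
            S[pi, c] = (sa + sb) / 2
            N[pi, c] = (na + nb) / 2
            Sd[pi, c] = sd
            Nd[pi, c] = nd
    return S, N, Sd, Nd


def _mean_rates(S, N, Sd, Nd, cols: np.ndarray) -> tuple[float, float]:
    """Mean pairwise (dN, dS) over the given codon columns; pairs whose
    observed proportion is saturated (p >= 3/4) are dropped from the mean."""
    s = np.nansum(S[:, cols], axis=1)
    n = np.nansum(N[:, cols], axis=1)
    sd = np.nansum(Sd[:, cols], axis=1)
    nd = np.nansum(Nd[:, cols], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = np.where(s > 0, sd / s, np.nan)
        pn = np.where(n > 0, nd / n, np.nan)
        ds = np.where(ps < 0.75, -0.75 * np.log1p(-4 * ps / 3), np.nan)
        dn = np.where(pn < 0.75, -0.75 * np.log1p(-4 * pn / 3), np.nan)
    ok = np.isfinite(ds) & np.isfinite(dn)
    if not ok.any():
        return float("nan"), float("nan")
    return float(dn[ok].mean()), float(ds[ok].mean())


def partition_rates(
    seqs: Sequence[str],
    pbs_mask: Sequence[int] | None = None,
    partition: str = "All",
    frame: int = 0,
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> SelectionSummary:
    """Mean pairwise dN and dS over a codon partition, with a one-tailed
    Z-test of positive selection (HA: dN > dS).

    ``partition`` is one of ``All``, ``PBS``, ``non-PBS``; the latter two
    need ``pbs_mask`` (1-based codon indices). Standard errors and the Z
    variance come from ``bootstrap_reps`` resamples of codon columns.
    """
    codon_rows = [to_codons(s, frame) for s in seqs]
    if len(codon_rows) < 2:
        raise ValueError("need at least 2 sequences")
    L = len(codon_rows[0])
    cols = _partition_columns(L, pbs_mask, partition)
    if len(cols) == 0:
        raise ValueError(f"empty partition {partition!r}")
    S, N, Sd, Nd = _pair_codon_tables(codon_rows)
    dn, ds = _mean_rates(S, N, Sd, Nd, cols)

    rng = np.random.default_rng(seed)
    boot_dn = np.empty(bootstrap_reps)
    boot_ds = np.empty(bootstrap_reps)
    for r in range(bootstrap_reps):
        resampled = rng.choice(cols, size=len(cols), replace=True)
        boot_dn[r], boot_ds[r] = _mean_rates(S, N, Sd, Nd, resampled)
    dn_se = float(np.nanstd(boot_dn, ddof=1))
    ds_se = float(np.nanstd(boot_ds, ddof=1))
    var = np.nanvar(boot_dn, ddof=1) + np.nanvar(boot_ds, ddof=1)
    if var == 0 or not np.isfinite(var):
        if dn == ds:
            z, p = 0.0, 0.5
        else:
            z = math.inf if dn > ds else -math.inf
            p = 0.0 if dn > ds else 1.0
            warnings.warn("zero bootstrap variance; p reported at boundary")
    else:
        z = (dn - ds) / math.sqrt(var)
        p = float(norm.sf(z))
    ratio = dn / ds if ds > 0 else float("inf") if dn > 0 else float("nan")
    return SelectionSummary(
        partition=partition,
        n_codons=len(cols),
        dN=dn,
        dN_se=dn_se,
        dS=ds,
        dS_se=ds_se,
        dn_ds=ratio,
        z=float(z),
        p_value=float(p),
    )


def _partition_columns(
    n_codons: int, pbs_mask: Sequence[int] | None, partition: str
) -> np.ndarray:
    if partition == "All":
        return np.arange(n_codons)
    if pbs_mask is None:
        raise ValueError("PBS/non-PBS partitions need a pbs_mask")
    pbs = np.array(sorted({i - 1 for i in pbs_mask if 1 <= i <= n_codons}), dtype=int)
    if partition == "PBS":
        return pbs
    if partition == "non-PBS":
        return np.setdiff1d(np.arange(n_codons), pbs)
    raise ValueError(f"unknown partition {partition!r}")


def z_test(
    seqs: Sequence[str],
    pbs_mask: Sequence[int] | None = None,
    partition: str = "All",
    frame: int = 0,
    reps: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """(Z, one-tailed p) of positive selection on a partition."""
    s = partition_rates(
        seqs, pbs_mask, partition, frame, bootstrap_reps=reps, seed=seed
    )
    return s.z, s.p_value


def selection_table(
    seqs: Sequence[str],
    pbs_mask: Sequence[int],
    frame: int = 0,
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> list[SelectionSummary]:
    """All / PBS / non-PBS summary rows for one locus alignment."""
    return [
        partition_rates(seqs, pbs_mask, part, frame, bootstrap_reps, seed)
        for part in ("All", "PBS", "non-PBS")
    ]
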