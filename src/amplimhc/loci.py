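"""Assignment of called alleles to loci and copy-number summaries.

With several recently duplicated loci (two of them co-amplified by one
primer pair) an allele cannot be assigned to its locus from the amplicon it
came from; assignment relies on sequence similarity to per-locus reference
alleles, helped by a diagnostic 3-nt deletion carried by every allele of
the third locus ("C"). Gene conversion between paralogues can blur this
signal, so the assignment records its confidence margin and falls back to
``unassigned`` on conflicts and ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from ._seq import aligned_p_distance


@dataclass(frozen=True)
class LocusAssignment:
    allele: str
    locus: str  # reference locus label or "unassigned"
    distance: float  # p-distance to the nearest reference
    margin: float  # second-best minus best distance (inf with one locus)
    deletion_flag: bool  # diagnostic 3' 3-nt deletion detected


def _has_3nt_deletion(seq: str, reference: str) -> bool:
    """True when the query runs at least 3 nt short of a deletion-free
    reference. Length difference is used rather than a gap-position scan:
    optimal-alignment gap placement is not unique, but an exon-2 allele of
    the deletion-bearing locus is always >=3 nt shorter than the
    deletion-free loci, and called alleles carry no other indels."""
    return len(reference) - len(seq) >= 3


def assign_locus(
    sequence: str,
    references: Mapping[str, Sequence[str] | str],
    *,
    tie_tolerance: float = 0.01,
    deletion_locus: str = "C",
    allele: str = "",
) -> LocusAssignment:
    """Assign one allele to the locus of its nearest reference.

    ``references`` maps locus label -> reference sequence(s). p-distances
    use global alignment with pairwise deletion of gap columns. Ties within
    ``tie_tolerance`` between the two best loci give ``unassigned``; a
    detected diagnostic 3-nt deletion forces the deletion locus, and a
    conflict (deletion present but another locus nearest) also gives
    ``unassigned``.
    """
    if not references:
        raise ValueError("reference panel is empty")
    per_locus: dict[str, float] = {}
    for locus, refs in references.items():
        seqs = [refs] if isinstance(refs, str) else list(refs)
        per_locus[locus] = min(aligned_p_distance(sequence, r) for r in seqs)
    ranked = sorted(per_locus.items(), key=lambda kv: (kv[1], kv[0]))
    best_locus, best_d = ranked[0]
    margin = ranked[1][1] - best_d if len(ranked) > 1 else float("inf")

    deletion = False
    nondel_refs = [
        (refs if isinstance(refs, str) else refs[0])
        for locus, refs in references.items()
        if locus != deletion_locus
    ]
    if deletion_locus in references and nondel_refs:
        deletion = _has_3nt_deletion(sequence, nondel_refs[0])

    label = best_locus
    if margin < tie_tolerance:
        label = "unassigned"
    if deletion and best_locus != deletion_locus:
        label = "unassigned"
    elif deletion:
        label = deletion_locus
    return LocusAssignment(
        allele=allele, locus=label, distance=best_d, margin=margin, deletion_flag=deletion
    )


def assign_all(
    sequences: Mapping[str, str],
    references: Mapping[str, Sequence[str] | str],
    **kwargs,
) -> pd.DataFrame:
    """Assign every allele; returns a DataFrame indexed by allele id."""
    rows = [
        assign_locus(seq, references, allele=aid, **kwargs).__dict__
        for aid, seq in sequences.items()
    ]
    return pd.DataFrame(rows).set_index("allele")


def cnv_summary(genotypes: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Distribution of allele counts per individual, per locus and overall.

    ``genotypes`` is long-form with columns ``individual``, ``allele``,
    ``locus``. Returns per-locus and overall count tables with the fraction
    of individuals at each count value (the copy-number profile).
    """
    required = {"individual", "allele", "locus"}
    if not required <= set(genotypes.columns):
        raise ValueError(f"genotypes must have columns {sorted(required)}")
    individuals = genotypes["individual"].unique()
    n = len(individuals)

    def distribution(counts: pd.Series) -> pd.DataFrame:
        counts = counts.reindex(individuals, fill_value=0)
        dist = counts.value_counts().sort_index()
        return pd.DataFrame(
            {"n_individuals": dist, "fraction": dist / n}
        ).rename_axis("n_alleles")

    out: dict[str, pd.DataFrame] = {}
    for locus, sub in genotypes.groupby("locus"):
        out[str(locus)] = distribution(sub.groupby("individual")["allele"].nunique())
    out["all"] = distribution(genotypes.groupby("individual")["allele"].nunique())
    return out
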