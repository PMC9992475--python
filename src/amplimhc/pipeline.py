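"""End-to-end orchestration: simulate -> genotype -> assign loci ->
diversity / selection / recombination / rarefaction.

Each stage writes its plain-text artifacts into an output directory and a
structured log records every filter decision, so a complete audit trail of
why each variant was kept or rejected survives the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as aio
from .diversity import diversity_summary, infer_frame
from .genotyping import (
    FilterConfig,
    GenotypeCall,
    filter_cascade,
    genotyping_accuracy,
    replicate_concordance,
)
from .loci import assign_all, cnv_summary
from .rarefaction import accumulation_by_cohort
from .recombination import four_gamete_rm, phi_test
from .selection import load_pbs_mask, selection_table
from .simulate import (
    ASVTable,
    SimulationConfig,
    TruthSet,
    primer_sets_for,
    simulate_experiment,
)

log = logging.getLogger("amplimhc")


@dataclass
class PipelineResult:
    outdir: Path
    calls: list[GenotypeCall]
    genotype_table: pd.DataFrame
    assignments: pd.DataFrame
    concordance: float
    accuracy: dict[str, float] | None = None
    diversity: dict[str, object] = field(default_factory=dict)
    selection: dict[str, list] = field(default_factory=dict)
    recombination: dict[str, object] = field(default_factory=dict)
    rarefaction: dict[str, pd.DataFrame] = field(default_factory=dict)


def consensus_genotypes(calls: list[GenotypeCall]) -> pd.DataFrame:
    """One row per (individual, primer set): the union of alleles called
    across its usable replicate amplicons."""
    rows: dict[tuple[str, str], set[str]] = {}
    for c in calls:
        if c.status == "discarded_low_coverage":
            continue
        rows.setdefault((c.individual, c.primer_set), set()).update(c.called)
    return pd.DataFrame(
        [
            {"individual": ind, "primer_set": ps, "alleles": sorted(al)}
            for (ind, ps), al in sorted(rows.items())
        ]
    )


def run_pipeline(
    outdir,
    sim_config: SimulationConfig | None = None,
    table: ASVTable | None = None,
    references: dict[str, str] | None = None,
    filter_config: FilterConfig | None = None,
    truth: TruthSet | None = None,
    pbs_mask_path=None,
    rarefaction_reps: int = 500,
    bootstrap_reps: int = 1000,
    phi_permutations: int = 1000,
    seed: int = 0,
) -> PipelineResult:
    """Run every stage on either a simulated experiment (``sim_config``) or
    a user-supplied ASV table plus per-locus references.

    Returns the in-memory results; all tables are also written under
    ``outdir`` (1-based inclusive coordinates in every TSV).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if sim_config is not None:
        registry, truth, table = simulate_experiment(sim_config)
        references = dict(registry.founders)
        aio.write_fasta(outdir / "allele_registry.fasta", registry.sequences)
        aio.write_asv_table(table, outdir / "asv")
        n_loci = sim_config.n_loci
    elif table is None or references is None:
        raise ValueError("need either sim_config or (table, references)")
    else:
        n_loci = len(references)

    psets = primer_sets_for(n_loci)
    fcfg = filter_config or FilterConfig(
        max_expected_alleles={ps: 2 * len(loci) for ps, loci in psets.items()}
    )
    calls = filter_cascade(table, references, fcfg)
    log.info(
        "genotyping: %d amplicons, %d ok, %d low coverage, %d unclear",
        len(calls),
        sum(c.status == "ok" for c in calls),
        sum(c.status == "discarded_low_coverage" for c in calls),
        sum(c.status == "unclear" for c in calls),
    )
    geno_table, audit = aio.calls_to_tables(calls)
    aio.write_table(outdir / "genotypes.tsv", geno_table)
    aio.write_table(outdir / "rejection_audit.tsv", audit)

    report = replicate_concordance(calls)
    aio.write_table(
        outdir / "replicate_report.tsv",
        pd.DataFrame(
            [
                {
                    "pairs_compared": report.pairs_compared,
                    "identical": report.identical,
                    "concordance": report.concordance,
                }
            ]
        ),
    )

    accuracy = None
    if truth is not None:
        accuracy = genotyping_accuracy(calls, truth, psets)
        log.info("accuracy vs truth: %s", accuracy)

    # ---- locus assignment on the called alleles
    called_ids = sorted({v for c in calls for v in c.called})
    called_seqs = {v: table.sequences[v] for v in called_ids}
    assignments = assign_all(called_seqs, references)
    aio.write_table(outdir / "locus_assignments.tsv", assignments.reset_index())

    long_rows = []
    for c in calls:
        if c.status == "discarded_low_coverage":
            continue
        for v in c.called:
            long_rows.append(
                {
                    "individual": c.individual,
                    "allele": v,
                    "locus": assignments.at[v, "locus"],
                }
            )
    long_geno = pd.DataFrame(long_rows).drop_duplicates()
    cnv = cnv_summary(long_geno) if len(long_geno) else {}
    for name, df in cnv.items():
        aio.write_table(outdir / f"cnv_{name}.tsv", df.reset_index())

    # ---- per-locus alignments of called alleles (sequences are generated
    # from a common frame-0 ancestor, so within a locus rows align as-is)
    result = PipelineResult(
        outdir=outdir,
        calls=calls,
        genotype_table=geno_table,
        assignments=assignments,
        concordance=report.concordance,
        accuracy=accuracy,
    )
    mask = load_pbs_mask(pbs_mask_path)
    for locus in sorted(set(assignments["locus"]) - {"unassigned"}):
        ids = [v for v in called_ids if assignments.at[v, "locus"] == locus]
        seqs = [called_seqs[v] for v in ids]
        if len(seqs) < 2 or len({len(s) for s in seqs}) != 1:
            continue
        frame = infer_frame(references[locus]) if locus in references else 0
        result.diversity[locus] = diversity_summary(seqs, frame=frame, ids=ids)
        result.selection[locus] = selection_table(
            seqs, mask, frame=frame, bootstrap_reps=bootstrap_reps, seed=seed
        )
        result.recombination[locus] = {
            "rm": four_gamete_rm(seqs),
            "phi": phi_test(seqs, permutations=phi_permutations, seed=seed),
        }
    _write_stat_tables(result, outdir)

    # ---- rarefaction cohorts
    geno_by_ps: dict[str, dict[str, set[str]]] = {}
    for c in calls:
        if c.status == "discarded_low_coverage":
            continue
        geno_by_ps.setdefault(c.primer_set, {}).setdefault(c.individual, set()).update(
            c.called
        )
    if geno_by_ps:
        curves = accumulation_by_cohort(geno_by_ps, reps=rarefaction_reps, seed=seed)
        result.rarefaction = curves.curves
        for name, df in curves.curves.items():
            aio.write_table(outdir / f"rarefaction_{name}.tsv", df)
    return result


def _write_stat_tables(result: PipelineResult, outdir: Path) -> None:
    if result.diversity:
        rows = []
        for locus, d in result.diversity.items():
            row = {"locus": locus}
            row.update(d.__dict__)
            rows.append(row)
        aio.write_table(outdir / "diversity_summary.tsv", pd.DataFrame(rows))
    if result.selection:
        rows = []
        for locus, summaries in result.selection.items():
            for s in summaries:
                row = {"locus": locus}
                row.update(s.__dict__)
                rows.append(row)
        aio.write_table(outdir / "selection_summary.tsv", pd.DataFrame(rows))
    if result.recombination:
        rows = []
        for locus, r in result.recombination.items():
            rm = r["rm"]
            phi = r["phi"]
            rows.append(
                {
                    "locus": locus,
                    "rm": rm.rm,
                    "intervals": ";".join(f"{a + 1}-{b + 1}" for a, b in rm.intervals),
                    "phi": phi.statistic,
                    "phi_p": phi.p_value,
                    "phi_computable": phi.computable,
                }
            )
        aio.write_table(outdir / "recombination_summary.tsv", pd.DataFrame(rows))
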