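"""Readers and writers for the pipeline's plain-text formats.

FASTA for sequences and alignments (Biopython), TSV for tables (pandas),
YAML for configuration. The ASV table round-trips as a TSV count matrix
(rows = variants, columns = amplicon ids) plus a variant FASTA and an
amplicon-metadata TSV.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotyping import GenotypeCall
from .simulate import ASVTable


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered {id: sequence}; raises on empty/malformed input."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta-2line")


def read_alignment(path) -> tuple[list[str], list[str]]:
    """Aligned FASTA -> (ids, rows); enforces uniform row length."""
    recs = read_fasta(path)
    ids, rows = list(recs), list(recs.values())
    if len({len(r) for r in rows}) > 1:
        raise ValueError(f"alignment rows in {path} have unequal lengths")
    return ids, rows


def read_table(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed TSV {path}: {exc}") from exc


def write_table(path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_asv_table(table: ASVTable, prefix) -> dict[str, Path]:
    """Write counts, variant sequences and amplicon metadata next to
    ``prefix``; returns the paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": prefix.with_suffix(".counts.tsv"),
        "sequences": prefix.with_suffix(".variants.fasta"),
        "amplicons": prefix.with_suffix(".amplicons.tsv"),
    }
    table.counts.rename_axis("variant").to_csv(paths["counts"], sep="\t")
    write_fasta(paths["sequences"], table.sequences)
    table.amplicons.rename_axis("amplicon").to_csv(paths["amplicons"], sep="\t")
    return paths


def read_asv_table(counts_path, fasta_path, amplicons_path) -> ASVTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts.empty:
        raise ValueError(f"empty ASV count table {counts_path}")
    sequences = read_fasta(fasta_path)
    amplicons = pd.read_csv(amplicons_path, sep="\t", index_col=0)
    table = ASVTable(sequences=sequences, counts=counts, amplicons=amplicons)
    table.validate()
    return table


def calls_to_tables(calls: Sequence[GenotypeCall]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(genotype table, rejection audit) in long form."""
    geno_rows = []
    audit_rows = []
    for c in calls:
        geno_rows.append(
            {
                "amplicon": c.amplicon,
                "individual": c.individual,
                "primer_set": c.primer_set,
                "status": c.status,
                "alleles": ",".join(c.called),
                "n_alleles": len(c.called),
            }
        )
        for v, reason in sorted(c.rejected.items()):
            audit_rows.append(
                {
                    "amplicon": c.amplicon,
                    "individual": c.individual,
                    "primer_set": c.primer_set,
                    "variant": v,
                    "reason": reason,
                }
            )
    audit = pd.DataFrame(
        audit_rows, columns=["amplicon", "individual", "primer_set", "variant", "reason"]
    )
    return pd.DataFrame(geno_rows), audit


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def dump_config(cfg: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)


def fasta_string(sequences: Mapping[str, str]) -> str:
    buf = _io.StringIO()
    for name, seq in sequences.items():
        buf.write(f">{name}\n{seq}\n")
    return buf.getvalue()
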