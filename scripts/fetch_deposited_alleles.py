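#!/usr/bin/env python
"""Download the 64 published catshark MHC IIβ exon-2 alleles
(GenBank OQ123732–OQ123795) into tests/data/scca_dbb_alleles.fasta.

Needs network access to NCBI; run once, then the published-value
regression tests in tests/test_deposited_regression.py become active.

Usage:
    python scripts/fetch_deposited_alleles.py [--out tests/data/scca_dbb_alleles.fasta]
"""

from __future__ import annotations

import argparse
import time
import urllib.parse
import urllib.request
from pathlib import Path

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
ACCESSIONS = [f"OQ{123732 + i}" for i in range(64)]


def fetch(ids: list[str]) -> str:
    params = urllib.parse.urlencode(
        {"db": "nuccore", "id": ",".join(ids), "rettype": "fasta", "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EUTILS}?{params}", timeout=60) as fh:
        return fh.read().decode()


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument(
        "--out",
        type=Path,
        default=Path(__file__).resolve().parent.parent
        / "tests"
        / "data"
        / "scca_dbb_alleles.fasta",
    )
    args = ap.parse_args()
    chunks = []
    for i in range(0, len(ACCESSIONS), 32):
        chunks.append(fetch(ACCESSIONS[i : i + 32]))
        time.sleep(0.5)  # NCBI rate limit courtesy
    text = "".join(chunks)
    n = text.count(">")
    if n != len(ACCESSIONS):
        raise SystemExit(f"expected {len(ACCESSIONS)} records, got {n}")
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(text)
    print(f"wrote {n} records to {args.out}")


if __name__ == "__main__":
    main()
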