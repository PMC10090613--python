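#!/usr/bin/env python
"""Fetch the deposited marker sequences from GenBank (network required).

The evidence fixture embeds the accession ranges of the deposited
sequences (cox1 OM456615-OM456680, ITS2 OM523325-OM523355,
28S OM459978-OM459997 plus the comparative/outgroup accessions). This
helper downloads them as plain FASTA so printed distance anchors (e.g.
35 cox1 differences between OM456635 and OM456679) can be recomputed on
the real data with `bivesdelim dist` / `bivesdelim otu`.

The pipeline itself never fetches anything; this is a one-time,
explicitly network-dependent convenience:

    python scripts/fetch_genbank.py --email you@example.org --out data/

Note the deposited sequences are unaligned; align them externally
(e.g. with mafft) before computing pairwise differences.
"""

from __future__ import annotations

import argparse
import re
import time
from pathlib import Path

from Bio import Entrez, SeqIO

from bivesdelim.study_fixture import ACCESSIONS


def expand(spec: str) -> list[str]:
    """Expand 'OM456615-OM456680' into the accession list."""
    m = re.fullmatch(r"([A-Z]+)(\d+)-(?:[A-Z]+)?(\d+)", spec)
    if not m:
        return [spec]
    prefix, lo, hi = m.group(1), m.group(2), m.group(3)
    width = len(lo)
    return [f"{prefix}{i:0{width}d}" for i in range(int(lo), int(hi) + 1)]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", required=True,
                        help="Contact email (NCBI requirement).")
    parser.add_argument("--out", type=Path, default=Path("data"),
                        help="Output directory for per-marker FASTA files.")
    parser.add_argument("--delay", type=float, default=0.4,
                        help="Seconds between requests.")
    args = parser.parse_args()

    Entrez.email = args.email
    args.out.mkdir(parents=True, exist_ok=True)
    for marker in ("cox1", "ITS2", "28S"):
        accs = expand(ACCESSIONS[marker])
        records = []
        for chunk_start in range(0, len(accs), 50):
            chunk = accs[chunk_start:chunk_start + 50]
            with Entrez.efetch(db="nucleotide", id=",".join(chunk),
                               rettype="fasta", retmode="text") as handle:
                records.extend(SeqIO.parse(handle, "fasta"))
            time.sleep(args.delay)
        path = args.out / f"{marker}.fasta"
        SeqIO.write(records, path, "fasta")
        print(f"{marker}: {len(records)} sequences -> {path}")


if __name__ == "__main__":
    main()
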