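#!/usr/bin/env python
"""Download the GenBank records for accession-based analyses (optional).

The core library is strictly offline; this helper exists so that users who
want to reproduce accession-linked divergence catalogs (e.g. the 18-SNP /
3-indel, 99.8%-identity comparison between two p2 allele regions, or the
335-aa spliced P2 translation) can fetch the deposited records once:

    python scripts/fetch_accessions.py --email you@example.org --out-dir data/

and then, for example:

    junctioneer convert --in data/HM454271.gb --out data/HM454271.fasta
    junctioneer compare data/HM454273.fasta data/HM454271.fasta --stdout

Requires network access; nothing in the package or its tests depends on it.
"""

import argparse
from pathlib import Path

ACCESSIONS = ["HM454271", "HM454272", "HM454273", "HM454274", "HM454275",
              "HM454276"]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--email", required=True,
                        help="contact email for NCBI Entrez")
    parser.add_argument("--out-dir", type=Path, default=Path("data"))
    args = parser.parse_args()

    from Bio import Entrez
    Entrez.email = args.email
    args.out_dir.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        dest = args.out_dir / f"{acc}.gb"
        if dest.exists():
            print(f"{dest} exists, skipping")
            continue
        with Entrez.efetch(db="nucleotide", id=acc, rettype="gbwithparts",
                           retmode="text") as handle:
            dest.write_text(handle.read())
        print(f"wrote {dest}")


if __name__ == "__main__":
    main()
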