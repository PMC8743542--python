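#!/usr/bin/env python
"""Fetch the two S. rimosus ATCC 10970 replicon accessions from NCBI.

Network access is deliberately kept out of the library; run this script
once (it needs internet) to place GenBank flat files under
data/accessions/, after which `linarch.reproduce.reproduce_tirs()` and the
corresponding acceptance check can run offline.

Usage: python scripts/fetch_accessions.py [outdir]
"""

import os
import sys
import urllib.request

ACCESSIONS = ["NZ_CP048261.1", "NZ_CP048262.1"]
EUTILS = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=gbwithparts&retmode=text"
)


def main() -> None:
    outdir = sys.argv[1] if len(sys.argv) > 1 else os.path.join("data", "accessions")
    os.makedirs(outdir, exist_ok=True)
    for acc in ACCESSIONS:
        dest = os.path.join(outdir, f"{acc}.gbff")
        if os.path.exists(dest):
            print(f"{dest} already present, skipping")
            continue
        url = EUTILS.format(acc=acc)
        print(f"fetching {acc} ...")
        with urllib.request.urlopen(url) as resp, open(dest, "wb") as fh:
            while chunk := resp.read(1 << 20):
                fh.write(chunk)
        print(f"wrote {dest}")


if __name__ == "__main__":
    main()
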