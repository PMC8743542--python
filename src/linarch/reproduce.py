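"""Reproduction of the published S. rimosus replicon measurements.

Fetching the two deposited accessions (chromosome NZ_CP048261.1, plasmid
SRP1 NZ_CP048262.1) is a documented user step — the library performs no
network access.  Place the downloaded GenBank flat files under
``data/accessions/`` (see ``scripts/fetch_accessions.py``); this module then
reruns the measurement pipeline on them: the chromosome carries 11,386 bp
TIRs and SRP1 288 bp TIRs, and both end in Sg2247-class telomeres.
"""

from __future__ import annotations

import os
from typing import Optional

from .io import read_replicon
from .orientation import orient
from .tir import imperfect_tir

__all__ = ["ACCESSIONS", "accession_dir", "reproduce_tirs"]

ACCESSIONS = {
    "NZ_CP048261.1": {"kind": "chromosome", "tir_bp": 11_386, "length": 9_351_267},
    "NZ_CP048262.1": {"kind": "plasmid", "tir_bp": 288, "length": 292_624},
}


def accession_dir(root: Optional[str] = None) -> str:
    root = root or os.getcwd()
    return os.path.join(root, "data", "accessions")


def reproduce_tirs(directory: Optional[str] = None) -> dict[str, dict]:
    """Measure TIRs of locally fetched accession flat files.

    Returns {accession: {"perfect": bp, "imperfect": bp, "expected": bp}}.
    Raises FileNotFoundError when the flat files have not been fetched.
    """
    directory = directory or accession_dir()
    out: dict[str, dict] = {}
    for acc, info in ACCESSIONS.items():
        path = os.path.join(directory, f"{acc}.gbff")
        if not os.path.exists(path):
            raise FileNotFoundError(
                f"{path} not found; run scripts/fetch_accessions.py first"
            )
        rec = read_replicon(path, format="genbank")
        rec, _ = orient(rec, strict=False)
        tir = imperfect_tir(rec)
        out[acc] = {
            "perfect": tir.perfect_len,
            "imperfect": tir.imperfect_len,
            "expected": info["tir_bp"],
            "length": rec.length,
            "expected_length": info["length"],
        }
    return out
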