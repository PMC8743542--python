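"""Reading and writing replicons and located features.

GenBank flat files and FASTA+GFF3 pairs are parsed with Biopython and
gffutils; everything is converted to the internal 0-based half-open
convention on the way in (GenBank and GFF3 are 1-based inclusive) and back to
each format's native convention on the way out.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    FeatureType,
    GeneAnnotation,
    RepliconRecord,
    Strand,
    normalize_gene_symbol,
)

__all__ = [
    "read_replicon",
    "write_replicon",
    "write_features",
    "LocatedFeature",
]

_FEATURE_TYPES = {
    "CDS": FeatureType.CDS,
    "tRNA": FeatureType.TRNA,
    "rRNA": FeatureType.RRNA,
    "ncRNA": FeatureType.NCRNA,
}


@dataclass(frozen=True)
class LocatedFeature:
    """A located, scored feature (e.g. a parS hit or an island interval)."""

    replicon_id: str
    start: int  # 0-based
    end: int  # half-open
    strand: str = "+"
    name: str = "feature"
    score: float = 0.0


class ParseError(ValueError):
    pass


def _strand(raw) -> Strand:
    if raw in (1, "+"):
        return Strand.PLUS
    if raw in (-1, "-"):
        return Strand.MINUS
    # GFF3 '.'/'?' strands: treat as plus; no pipeline stage depends on
    # strand of non-marker features.
    return Strand.PLUS


def _from_genbank(path: str) -> RepliconRecord:
    try:
        seqrec = next(SeqIO.parse(path, "genbank"))
    except StopIteration:
        raise ParseError(f"{path}: no GenBank records found") from None
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    topology = seqrec.annotations.get("topology", "linear")
    anns: list[GeneAnnotation] = []
    for feat in seqrec.features:
        ftype = _FEATURE_TYPES.get(feat.type)
        if ftype is None:
            continue
        quals = feat.qualifiers
        symbol = (quals.get("gene") or quals.get("locus_tag") or [None])[0]
        product = (quals.get("product") or [""])[0]
        start = int(feat.location.start)  # Biopython already 0-based
        end = int(feat.location.end)
        anns.append(
            GeneAnnotation(
                gene_symbol=normalize_gene_symbol(symbol, product, ftype),
                feature_type=ftype,
                start=start,
                end=end,
                strand=_strand(feat.location.strand),
                product=product,
            )
        )
    return RepliconRecord(
        id=seqrec.id,
        sequence=str(seqrec.seq),
        topology=topology if topology in ("linear", "circular") else "linear",
        annotations=anns,
        source=seqrec.id,
    )


def _from_fasta_gff3(fasta_path: str, gff3_path: str) -> RepliconRecord:
    try:
        seqrec = next(SeqIO.parse(fasta_path, "fasta"))
    except StopIteration:
        raise ParseError(f"{fasta_path}: no FASTA records found") from None
    try:
        db = gffutils.create_db(
            gff3_path,
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
        features = list(db.all_features())
    except gffutils.exceptions.EmptyInputError:
        features = []  # header-only GFF3: a replicon with no annotations
    anns: list[GeneAnnotation] = []
    for feat in features:
        ftype = _FEATURE_TYPES.get(feat.featuretype)
        if ftype is None:
            continue
        if feat.seqid != seqrec.id:
            continue
        symbol = (
            feat.attributes.get("gene", [None])[0]
            or feat.attributes.get("Name", [None])[0]
            or feat.attributes.get("locus_tag", [None])[0]
        )
        product = feat.attributes.get("product", [""])[0]
        start = feat.start - 1  # GFF3 1-based inclusive -> 0-based half-open
        end = feat.end
        if end > len(seqrec.seq):
            raise ParseError(
                f"{gff3_path}: feature [{feat.start}, {feat.end}] outside "
                f"sequence of length {len(seqrec.seq)}"
            )
        anns.append(
            GeneAnnotation(
                gene_symbol=normalize_gene_symbol(symbol, product, ftype),
                feature_type=ftype,
                start=start,
                end=end,
                strand=_strand(feat.strand),
                product=product,
            )
        )
    topology = "linear"
    with open(gff3_path) as fh:
        for line in fh:
            if line.startswith("##topology"):
                topology = line.split()[-1].strip()
            if not line.startswith("#"):
                break
    return RepliconRecord(
        id=seqrec.id,
        sequence=str(seqrec.seq),
        topology=topology,
        annotations=anns,
        source=seqrec.id,
    )


def read_replicon(path: str, format: str = "genbank", gff3: Optional[str] = None) -> RepliconRecord:
    """Read one replicon from a GenBank flat file or a FASTA+GFF3 pair.

    For ``format="fasta+gff3"``, ``path`` is the FASTA and ``gff3`` the
    annotation file (defaults to ``path`` with a ``.gff3`` suffix).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "genbank":
        return _from_genbank(path)
    if format == "fasta+gff3":
        if gff3 is None:
            gff3 = os.path.splitext(path)[0] + ".gff3"
        if not os.path.exists(gff3):
            raise FileNotFoundError(gff3)
        return _from_fasta_gff3(path, gff3)
    raise ValueError(f"unknown format {format!r}")


def write_replicon(rec: RepliconRecord, fasta_path: str, gff3_path: str) -> None:
    """Write a replicon as a FASTA + GFF3 pair (native 1-based GFF3 coords)."""
    SeqIO.write(
        SeqRecord(Seq(rec.sequence), id=rec.id, description=""),
        fasta_path,
        "fasta",
    )
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##topology {rec.topology}\n")
        fh.write(f"##sequence-region {rec.id} 1 {rec.length}\n")
        for i, a in enumerate(rec.annotations):
            attrs = [f"ID=feat{i}"]
            if a.gene_symbol:
                attrs.append(f"gene={a.gene_symbol}")
            if a.product:
                attrs.append(f"product={a.product}")
            fh.write(
                "\t".join(
                    [
                        rec.id,
                        "linarch",
                        a.feature_type.value,
                        str(a.start + 1),
                        str(a.end),
                        ".",
                        a.strand.value,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def write_features(
    hits: Sequence[LocatedFeature], path: str, format: str = "bed"
) -> None:
    """Write located features as BED (0-based half-open), GFF3 (1-based
    inclusive) or TSV; output stable-sorted by (replicon, start)."""
    ordered = sorted(hits, key=lambda h: (h.replicon_id, h.start))
    with open(path, "w") as fh:
        if format == "bed":
            fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
            for h in ordered:
                fh.write(
                    f"{h.replicon_id}\t{h.start}\t{h.end}\t{h.name}\t"
                    f"{h.score:g}\t{h.strand}\n"
                )
        elif format == "gff3":
            fh.write("##gff-version 3\n")
            for h in ordered:
                fh.write(
                    f"{h.replicon_id}\tlinarch\t{h.name}\t{h.start + 1}\t"
                    f"{h.end}\t{h.score:g}\t{h.strand}\t.\t.\n"
                )
        elif format == "tsv":
            fh.write("replicon\tstart\tend\tname\tscore\tstrand\n")
            for h in ordered:
                fh.write(
                    f"{h.replicon_id}\t{h.start}\t{h.end}\t{h.name}\t"
                    f"{h.score:g}\t{h.strand}\n"
                )
        else:
            raise ValueError(f"unknown feature format {format!r}")
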