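"""Core data model for linear replicons.

A :class:`RepliconRecord` carries the sequence of one replicon (chromosome or
giant linear plasmid) together with its gene annotations in a single internal
coordinate convention: 0-based, half-open, exactly as Python slices the
sequence string.  All downstream stages (orientation, TIR measurement,
telomere classification, parS scanning, origin-island delineation) operate on
this type only; format conversion happens at the I/O boundary.

Gene symbols are normalised to lowercase canonical tokens so that the
marker-gene logic (dnaA/dnaN/parA/parB for orientation, tRNA-Ile/dnaB as
island anchors) works across inconsistently annotated genomes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

__all__ = [
    "Strand",
    "FeatureType",
    "GeneAnnotation",
    "RepliconRecord",
    "normalize_gene_symbol",
    "reverse_complement",
    "CANONICAL_SYMBOLS",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N} (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"

    def flipped(self) -> "Strand":
        return Strand.MINUS if self is Strand.PLUS else Strand.PLUS


class FeatureType(str, Enum):
    CDS = "CDS"
    TRNA = "tRNA"
    RRNA = "rRNA"
    NCRNA = "ncRNA"
    OTHER = "other"


#: Canonical marker tokens recognised across the pipeline.
CANONICAL_SYMBOLS = frozenset(
    {
        "dnaa", "dnab", "dnan", "gyra", "gyrb", "reca", "recf",
        "para", "parb", "ssba", "tap", "tpg", "tac", "tpc", "ttra",
        "trna_ile",
    }
)

# Product-text patterns used when the annotation lacks a usable gene symbol.
# Editable: extend for cohorts with unusual annotation vocabularies.
_PRODUCT_PATTERNS: tuple[tuple[str, str], ...] = (
    (r"chromosomal replication initiat", "dnaa"),
    (r"replicative dna helicase", "dnab"),
    (r"dna polymerase iii.*beta", "dnan"),
    (r"beta sliding clamp", "dnan"),
    (r"gyrase.*subunit a", "gyra"),
    (r"gyrase.*subunit b", "gyrb"),
    (r"dna replication.*repair protein recf", "recf"),
    (r"partition.*atpase|soj|para\b", "para"),
    (r"partition.*parb|spo0j|parb\b", "parb"),
    (r"single-strand(ed)? dna-binding", "ssba"),
    (r"telomere-associated protein|telomere associated protein", "tap"),
    (r"terminal protein\b", "tpg"),
)

_SYMBOL_STRIP = re.compile(r"[_\-]?\d+$")


def normalize_gene_symbol(
    symbol: Optional[str],
    product: str = "",
    feature_type: FeatureType = FeatureType.CDS,
) -> Optional[str]:
    """Map an annotated gene symbol / product description to a canonical token.

    Matching is case-insensitive; copy suffixes (``dnaA_1``, ``parB-2``) are
    stripped.  A tRNA feature whose product mentions ``Ile`` maps to
    ``trna_ile`` regardless of its symbol.  Returns ``None`` when the feature
    matches no canonical token.
    """
    if feature_type is FeatureType.TRNA:
        if "ile" in product.lower() or (symbol or "").lower().startswith("trna-ile"):
            return "trna_ile"
        return None
    if symbol:
        tok = _SYMBOL_STRIP.sub("", symbol.strip().lower())
        if tok in CANONICAL_SYMBOLS:
            return tok
    prod = product.lower()
    for pat, tok in _PRODUCT_PATTERNS:
        if re.search(pat, prod):
            return tok
    return None


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated feature, 0-based half-open, on a parent replicon."""

    gene_symbol: Optional[str]
    feature_type: FeatureType
    start: int
    end: int
    strand: Strand
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid feature interval [{self.start}, {self.end})"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def flipped(self, length: int) -> "GeneAnnotation":
        """Remap onto the reverse complement of a replicon of ``length`` bp."""
        return replace(
            self,
            start=length - self.end,
            end=length - self.start,
            strand=self.strand.flipped(),
        )


@dataclass
class RepliconRecord:
    """A closed replicon: sequence plus ordered gene annotations."""

    id: str
    sequence: str
    topology: str = "linear"
    annotations: list[GeneAnnotation] = field(default_factory=list)
    source: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"sequence contains non-DNA characters: {bad}")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        for ann in self.annotations:
            if ann.end > len(self.sequence):
                raise ValueError(
                    f"annotation [{ann.start}, {ann.end}) outside replicon "
                    f"{self.id} of length {len(self.sequence)}"
                )
        self.annotations = sorted(self.annotations, key=lambda a: (a.start, a.end))

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_linear(self) -> bool:
        return self.topology == "linear"

    def features(self, symbol: str) -> list[GeneAnnotation]:
        """All annotations whose canonical symbol equals ``symbol`` (lowercased)."""
        sym = symbol.lower()
        return [a for a in self.annotations if a.gene_symbol == sym]

    def feature_nearest_midpoint(self, symbol: str) -> Optional[GeneAnnotation]:
        """The copy of ``symbol`` closest to the replicon midpoint.

        Marker paralogs near the telomeres (e.g. plasmid-style parA copies)
        would otherwise hijack orientation and oriC placement; the origin
        region of these taxa is central, so the central copy is taken.
        """
        hits = self.features(symbol)
        if not hits:
            return None
        mid = self.length / 2.0
        return min(hits, key=lambda a: (abs(a.midpoint - mid), a.start))

    def reverse_complemented(self) -> "RepliconRecord":
        return RepliconRecord(
            id=self.id,
            sequence=reverse_complement(self.sequence),
            topology=self.topology,
            annotations=[a.flipped(self.length) for a in self.annotations],
            source=self.source,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RepliconRecord):
            return NotImplemented
        return (
            self.id == other.id
            and self.sequence == other.sequence
            and self.topology == other.topology
            and self.annotations == other.annotations
        )


def require_linear(rec: RepliconRecord, what: str) -> None:
    """Raise for circular topology; architecture stages are linear-only."""
    if not rec.is_linear:
        raise ValueError(f"{what} undefined for circular replicons ({rec.id})")


def iter_symbols(anns: Iterable[GeneAnnotation]) -> list[str]:
    return [a.gene_symbol for a in anns if a.gene_symbol]
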