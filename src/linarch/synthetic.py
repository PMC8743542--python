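"""Synthetic linear replicons with planted architecture and exact truth.

The generator emulates a streptomycete chromosome: a high-GC (default 72%)
i.i.d. background flanked by class-specific 150-bp telomeres and terminal
inverted repeats of configurable perfect/imperfect extent, a central origin
island carrying the canonical gene cassette (tRNA-Ile ... gyrB, gyrA, recF,
dnaN, dnaA, parA, parB, ssbA ... dnaB) at a configurable fractional
position, and parS sites drawn from a weight matrix and placed with a
configurable right-replichore bias and island enrichment.  Every planted
coordinate is recorded in a :class:`SyntheticTruth`, so pipeline recovery
can be checked exactly.

Fractions (right bias, island fraction) are realised as exact rounded
counts rather than Bernoulli draws, so the planted composition of every
genome matches its configuration to rounding; realised counts are in the
truth table.  Identical (config, seed) gives byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .parsscan import WeightMatrix, load_default_matrix
from .records import (
    FeatureType,
    GeneAnnotation,
    RepliconRecord,
    Strand,
    reverse_complement,
)
from .telomeres import TELOMERE_CLASSES, TelomereReference, load_panel

__all__ = ["SyntheticConfig", "SyntheticTruth", "CohortTruth", "generate",
           "generate_cohort", "paper_cohort_config", "write_genome"]

_BASES = "ACGT"

# (symbol, feature type, length bp, strand) in island order; tRNA-Ile opens
# the island and dnaB closes it.  dnaN/dnaA run right-to-left, parA/parB
# left-to-right, matching the canonical orientation.
_CASSETTE = (
    ("trna_ile", FeatureType.TRNA, 76, Strand.PLUS),
    ("gyrb", FeatureType.CDS, 2000, Strand.MINUS),
    ("gyra", FeatureType.CDS, 2500, Strand.MINUS),
    ("recf", FeatureType.CDS, 1100, Strand.MINUS),
    ("dnan", FeatureType.CDS, 1100, Strand.MINUS),
    ("dnaa", FeatureType.CDS, 1400, Strand.MINUS),
    ("para", FeatureType.CDS, 1000, Strand.PLUS),
    ("parb", FeatureType.CDS, 1000, Strand.PLUS),
    ("ssba", FeatureType.CDS, 600, Strand.PLUS),
    ("dnab", FeatureType.CDS, 1400, Strand.PLUS),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of one synthetic replicon; defaults are the study conditions."""

    length: int = 8_846_536
    gc: float = 0.72
    telomere_class_left: str = "Sg2247"
    telomere_class_right: str = "Sg2247"
    tir_perfect: int = 37_990
    tir_imperfect_extra: int = 39_102
    tir_mutation_rate: float = 0.05
    island_fraction: float = 0.485
    island_size: int = 50_000
    n_pars: int = 23
    pars_right_bias: float = 0.8
    pars_in_island_fraction: float = 0.45
    consensus_only: bool = False
    replicon_id: str = "synthetic"

    def validate(self) -> None:
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0, 1)")
        if not (0.0 < self.island_fraction < 1.0):
            raise ValueError("island_fraction must be in (0, 1)")
        for cls in (self.telomere_class_left, self.telomere_class_right):
            if cls not in TELOMERE_CLASSES:
                raise ValueError(f"unknown telomere class {cls!r}")
        same = self.telomere_class_left == self.telomere_class_right
        if same and 0 < self.tir_perfect < 150:
            raise ValueError(
                "identical telomere classes at both ends imply a perfect TIR "
                "of at least the 150 bp telomere; set tir_perfect >= 150"
            )
        if not same and (self.tir_perfect or self.tir_imperfect_extra):
            raise ValueError(
                "a nonzero TIR requires the same telomere class at both ends"
            )
        tir_total = self.tir_perfect + self.tir_imperfect_extra
        mid = self.island_fraction * self.length
        start = int(round(mid - self.island_size / 2))
        end = start + self.island_size
        if start < tir_total + 1000 or end > self.length - tir_total - 1000:
            raise ValueError(
                "island does not fit between the TIR blocks; "
                "increase length or shrink the TIRs/island"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth; all coordinates 0-based half-open."""

    seed: int
    replicon_id: str
    length: int
    telomere_class_left: str
    telomere_class_right: str
    tir_perfect: int
    tir_imperfect: int
    island: tuple[int, int]
    oric_pos: int
    pars_positions: list[int] = field(default_factory=list)
    pars_strands: list[str] = field(default_factory=list)
    n_left: int = 0
    n_right: int = 0
    n_in_island: int = 0
    island_location_pct: float = 0.0
    island_pct_of_chromosome: float = 0.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


@dataclass
class CohortTruth:
    seed: int
    truths: list[SyntheticTruth]
    means: dict[str, float]


def _panel_by_class() -> dict[str, TelomereReference]:
    return {ref.class_id: ref for ref in load_panel()}


def _background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.int8)


_ENC = {b: i for i, b in enumerate(_BASES)}


def _encode(seq: str) -> np.ndarray:
    return np.array([_ENC[c] for c in seq], dtype=np.int8)


def _decode(arr: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[arr.astype(np.intp)].tobytes().decode("ascii")


def _place_cassette(cfg: SyntheticConfig) -> tuple[list[GeneAnnotation], int, tuple[int, int]]:
    """Deterministic gene placement inside the island; returns
    (annotations, oriC position, island interval)."""
    mid = cfg.island_fraction * cfg.length
    start = int(round(mid - cfg.island_size / 2))
    end = start + cfg.island_size
    total_genes = sum(g[2] for g in _CASSETTE)
    n_gaps = len(_CASSETTE) - 1
    slack = cfg.island_size - total_genes
    if slack < n_gaps:
        raise ValueError("island_size too small for the gene cassette")
    gap, extra = divmod(slack, n_gaps)
    anns: list[GeneAnnotation] = []
    pos = start
    oric = None
    for k, (sym, ftype, glen, strand) in enumerate(_CASSETTE):
        if k == len(_CASSETTE) - 1:
            pos = end - glen  # dnaB closes the island exactly
        a = GeneAnnotation(sym, ftype, pos, pos + glen, strand,
                           product=sym)
        anns.append(a)
        if sym == "dnaa":
            oric = a.start  # last transcribed base of dnaA on '-'
        pos += glen + gap + (1 if k < extra else 0)
    assert oric is not None
    return anns, oric, (start, end)


def _free_intervals(lo: int, hi: int, blocked: list[tuple[int, int]], width: int):
    """Sub-intervals of [lo, hi) of length >= width not touching blocked."""
    out = []
    cur = lo
    for s, e in sorted(blocked):
        if e <= lo or s >= hi:
            continue
        if s - cur >= width:
            out.append((cur, min(s, hi)))
        cur = max(cur, e)
    if hi - cur >= width:
        out.append((cur, hi))
    return out


def _sample_positions(
    rng: np.random.Generator,
    intervals: list[tuple[int, int]],
    n: int,
    width: int,
    taken: list[int],
    max_tries: int = 2000,
) -> list[int]:
    """Rejection-sample n non-overlapping site starts within intervals."""
    spans = np.maximum(
        np.array([e - s - width + 1 for s, e in intervals], dtype=float), 0.0
    )
    if n and (not intervals or spans.sum() <= 0):
        raise ValueError("no room to place parS sites; increase length")
    placed: list[int] = []
    for _ in range(n):
        for _try in range(max_tries):
            iv = int(rng.choice(len(intervals), p=spans / spans.sum()))
            s, e = intervals[iv]
            pos = int(rng.integers(s, e - width + 1))
            if all(abs(pos - q) >= width for q in taken + placed):
                placed.append(pos)
                break
        else:
            raise ValueError("could not place parS sites without overlap")
    return placed


def generate(
    cfg: SyntheticConfig = SyntheticConfig(),
    seed: int = 0,
    matrix: Optional[WeightMatrix] = None,
) -> tuple[RepliconRecord, SyntheticTruth]:
    """Generate one synthetic replicon and its truth table."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    if matrix is None:
        matrix = load_default_matrix()
    panel = _panel_by_class()
    L = cfg.length
    arr = _background(rng, L, cfg.gc)

    # telomeres in 3'-overhang convention: right end carries the reference
    # verbatim, left end its reverse complement
    left_ref = panel[cfg.telomere_class_left].seq150
    right_ref = panel[cfg.telomere_class_right].seq150
    arr[: len(left_ref)] = _encode(reverse_complement(left_ref))
    arr[L - len(right_ref):] = _encode(right_ref)

    tir_total = cfg.tir_perfect + cfg.tir_imperfect_extra
    if tir_total > 0:
        block = arr[:tir_total].copy()
        right = (3 - block)[::-1]  # reverse complement in code space
        # mutate the copy beyond the perfect core; the first base past the
        # core is always mutated so the planted perfect length is exact
        ncore = cfg.tir_perfect
        tail = np.arange(ncore, tir_total)
        mutate = rng.random(tail.size) < cfg.tir_mutation_rate
        if tail.size:
            mutate[0] = True
        for k in tail[mutate]:
            # position of block[k] inside the right copy
            j = tir_total - 1 - k
            right[j] = (right[j] + int(rng.integers(1, 4))) % 4
        arr[L - tir_total:] = right
        tir_perfect_truth = cfg.tir_perfect
    else:
        # different telomere classes: make sure the extreme bases cannot
        # seed a spurious 1-bp repeat, so the planted perfect length is 0
        if int(arr[L - 1]) == 3 - int(arr[0]):
            arr[L - 1] = (arr[L - 1] + 1) % 4
        tir_perfect_truth = 0

    anns, oric, island = _place_cassette(cfg)

    # parS sites: exact rounded counts per replichore and compartment
    n = cfg.n_pars
    n_right = int(round(cfg.pars_right_bias * n))
    n_left = n - n_right
    n_isl_right = int(round(cfg.pars_in_island_fraction * n_right))
    n_isl_left = int(round(cfg.pars_in_island_fraction * n_left))
    w = matrix.width
    gene_blocks = [(a.start, a.end) for a in anns]
    margin = tir_total + 200
    isl_l = _free_intervals(island[0], oric, gene_blocks, w)
    isl_r = _free_intervals(oric + 1, island[1], gene_blocks, w)
    bulk_l = [(margin, island[0])]
    bulk_r = [(island[1], L - margin - w)]
    taken: list[int] = []
    groups = (
        (isl_l, n_isl_left, True),
        (bulk_l, n_left - n_isl_left, True),
        (isl_r, n_isl_right, False),
        (bulk_r, n_right - n_isl_right, False),
    )
    positions: list[int] = []
    strands: list[str] = []
    for intervals, count, _is_left in groups:
        pls = _sample_positions(rng, intervals, count, w, taken)
        taken.extend(pls)
        for pos in pls:
            site = matrix.consensus if cfg.consensus_only else matrix.sample_site(rng)
            strand = "+" if rng.random() < 0.5 else "-"
            planted = site if strand == "+" else reverse_complement(site)
            arr[pos:pos + w] = _encode(planted)
            positions.append(pos)
            strands.append(strand)
    order = np.argsort(positions, kind="stable")
    positions = [positions[i] for i in order]
    strands = [strands[i] for i in order]

    rec = RepliconRecord(
        id=cfg.replicon_id,
        sequence=_decode(arr),
        topology="linear",
        annotations=anns,
    )
    truth = SyntheticTruth(
        seed=seed,
        replicon_id=cfg.replicon_id,
        length=L,
        telomere_class_left=cfg.telomere_class_left,
        telomere_class_right=cfg.telomere_class_right,
        tir_perfect=tir_perfect_truth,
        tir_imperfect=tir_total,
        island=island,
        oric_pos=oric,
        pars_positions=positions,
        pars_strands=strands,
        n_left=sum(1 for p in positions if p <= oric),
        n_right=sum(1 for p in positions if p > oric),
        n_in_island=sum(1 for p in positions if island[0] <= p < island[1]),
        island_location_pct=100.0 * ((island[0] + island[1]) / 2.0) / L,
        island_pct_of_chromosome=100.0 * (island[1] - island[0]) / L,
    )
    return rec, truth


def paper_cohort_config(rng: np.random.Generator, index: int) -> SyntheticConfig:
    """Draw one cohort genome's configuration.

    Jitter distributions (uniform unless noted) are chosen so the cohort
    means reproduce the study conditions: length mean 8,846,536 bp, island
    size mean 51,055 bp, island midpoint fraction U(0.4125, 0.5325), perfect
    TIR mean 37,990 bp, imperfect extension mean 39,102 bp, parS count mean
    23.  Telomere classes favour the archetypal end, with both ends of a
    replicon sharing a class.
    """
    cls = str(rng.choice(
        list(TELOMERE_CLASSES),
        p=[0.5, 0.075, 0.075, 0.2, 0.075, 0.075],
    ))
    return SyntheticConfig(
        length=int(rng.integers(6_841_649, 10_851_424)),
        telomere_class_left=cls,
        telomere_class_right=cls,
        tir_perfect=int(rng.integers(150, 75_831)),
        tir_imperfect_extra=int(rng.integers(0, 78_205)),
        island_fraction=float(rng.uniform(0.4125, 0.5325)),
        island_size=int(rng.integers(48_019, 54_092)),
        n_pars=int(rng.integers(11, 36)),
        replicon_id=f"synthetic_{index:02d}",
    )


def generate_cohort(
    n: int,
    seed: int = 0,
    template: Optional[SyntheticConfig] = None,
    matrix: Optional[WeightMatrix] = None,
):
    """Generate n genomes; yields (RepliconRecord, SyntheticTruth) lazily.

    With ``template=None`` each genome draws the paper-cohort jitter; a
    template config is reused verbatim (only the id and seed vary).
    Per-genome seeds derive from ``seed`` via SeedSequence spawning, so a
    cohort is reproducible as a whole and genome-by-genome.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if matrix is None:
        matrix = load_default_matrix()
    children = np.random.SeedSequence(seed).spawn(n + 1)
    cfg_rng = np.random.default_rng(children[0])
    for i in range(n):
        if template is None:
            cfg = paper_cohort_config(cfg_rng, i)
        else:
            cfg = dataclasses.replace(template, replicon_id=f"{template.replicon_id}_{i:02d}")
        sub_seed = int(children[i + 1].generate_state(1)[0] % (2**31))
        yield generate(cfg, seed=sub_seed, matrix=matrix)


def cohort_truth_means(truths: list[SyntheticTruth]) -> dict[str, float]:
    """Exact means of the planted per-genome metrics."""
    n = len(truths)
    def mean(vals):
        return float(sum(vals) / n)
    return {
        "length": mean([t.length for t in truths]),
        "tir_perfect": mean([t.tir_perfect for t in truths]),
        "tir_imperfect": mean([t.tir_imperfect for t in truths]),
        "island_size": mean([t.island[1] - t.island[0] for t in truths]),
        "island_location_pct": mean([t.island_location_pct for t in truths]),
        "island_pct_of_chromosome": mean([t.island_pct_of_chromosome for t in truths]),
        "n_pars": mean([len(t.pars_positions) for t in truths]),
        "pct_right": mean(
            [100.0 * t.n_right / len(t.pars_positions) for t in truths]
        ),
        "pct_in_island": mean(
            [100.0 * t.n_in_island / len(t.pars_positions) for t in truths]
        ),
    }


def write_genome(rec: RepliconRecord, truth: SyntheticTruth, outdir: str) -> dict[str, str]:
    """Write FASTA + GFF3 + truth JSON for one genome; returns the paths."""
    from .io import write_replicon

    os.makedirs(outdir, exist_ok=True)
    fasta = os.path.join(outdir, f"{rec.id}.fasta")
    gff3 = os.path.join(outdir, f"{rec.id}.gff3")
    tjson = os.path.join(outdir, f"{rec.id}.truth.json")
    write_replicon(rec, fasta, gff3)
    with open(tjson, "w") as fh:
        fh.write(truth.to_json() + "\n")
    return {"fasta": fasta, "gff3": gff3, "truth": tjson}
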