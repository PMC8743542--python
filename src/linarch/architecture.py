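"""oriC location, origin-island delineation and parS distribution statistics.

On an oriented replicon (dnaA/dnaN on '-', parA/parB on '+') the replication
origin is operationalised as the last transcribed base of dnaA — the
left-most genomic coordinate of the dnaA CDS, since dnaA runs right-to-left
after orientation.  The origin island is the interval from the nearest
tRNA-Ile gene left of oriC to the end of the nearest dnaB gene right of
oriC; across streptomycete chromosomes it is a ~50 kb syntenic block holding
gyrB, gyrA, recF, dnaN, oriC, dnaA, parA, parB and ssbA.  parS statistics
split hits into left/right replichores at oriC and into island vs bulk
compartments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .parsscan import ParSHit
from .records import RepliconRecord

__all__ = [
    "OriginIslandResult",
    "ParSStats",
    "RepliconSummary",
    "CohortSummary",
    "locate_oric",
    "delineate_island",
    "pars_statistics",
    "summarize_cohort",
]

log = logging.getLogger(__name__)

ISLAND_GENE_ORDER = (
    "trna_ile", "gyrb", "gyra", "recf", "dnan", "dnaa",
    "para", "parb", "ssba", "dnab",
)


class MissingAnchorError(ValueError):
    pass


@dataclass(frozen=True)
class OriginIslandResult:
    replicon_id: str
    oric_pos: int
    island: tuple[int, int]  # [start, end), 0-based half-open
    size: int
    pct_of_chromosome: float
    location_pct: float  # island midpoint as percent of length (default mode)
    gene_order: tuple[str, ...]


@dataclass(frozen=True)
class ParSStats:
    n_sites: int
    pct_left: Optional[float]
    pct_right: Optional[float]
    pct_in_island: Optional[float]
    mean_gap_island: Optional[float]
    mean_gap_bulk: Optional[float]


@dataclass
class RepliconSummary:
    """Per-replicon architecture metrics, missing values as None."""

    replicon_id: str
    length: int
    kind: str = "chromosome"  # or "plasmid"
    oriented: bool = True
    telomere_left: Optional[str] = None
    telomere_right: Optional[str] = None
    tir_perfect: Optional[int] = None
    tir_imperfect: Optional[int] = None
    oric_pos: Optional[int] = None
    island: Optional[OriginIslandResult] = None
    pars: Optional[ParSStats] = None
    errors: dict[str, str] = field(default_factory=dict)


@dataclass
class CohortSummary:
    n_chromosomes: int
    n_plasmids: int
    means: dict[str, float]
    ranges: dict[str, tuple[float, float]]
    plasmid_means: dict[str, float] = field(default_factory=dict)
    plasmid_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)


def locate_oric(rec: RepliconRecord) -> int:
    """oriC = last base of dnaA on the oriented replicon.

    dnaA lies on '-' after orientation, so its last transcribed base (the
    3' end of the CDS) is the left-most genomic coordinate of the feature.
    With several dnaA copies the one nearest the midpoint is used.
    """
    copies = rec.features("dnaa")
    if not copies:
        raise MissingAnchorError(f"oriC undefined: no dnaA annotated on {rec.id}")
    if len(copies) > 1:
        log.warning("%d dnaA copies on %s; using the most central", len(copies), rec.id)
    ann = rec.feature_nearest_midpoint("dnaa")
    return ann.start if ann.strand.value == "-" else ann.end - 1


def delineate_island(
    rec: RepliconRecord,
    oric: Optional[int] = None,
    search_window: int = 200_000,
    location_mode: str = "midpoint",
) -> OriginIslandResult:
    """Delineate the origin island around oriC.

    Left anchor: start of the nearest tRNA-Ile feature left of oriC within
    ``search_window`` bp; right anchor: end of the nearest dnaB CDS right of
    oriC within the window.  ``location_mode`` selects whether the reported
    location percent uses the island midpoint (default) or its start.
    """
    if oric is None:
        oric = locate_oric(rec)
    lefts = [
        a for a in rec.features("trna_ile")
        if a.start <= oric and oric - a.start <= search_window
    ]
    if not lefts:
        raise MissingAnchorError(
            f"no tRNA-Ile anchor within {search_window} bp left of oriC on {rec.id}"
        )
    left = max(lefts, key=lambda a: a.start)
    rights = [
        a for a in rec.features("dnab")
        if a.end > oric and a.end - oric <= search_window
    ]
    if not rights:
        raise MissingAnchorError(
            f"no dnaB anchor within {search_window} bp right of oriC on {rec.id}"
        )
    right = min(rights, key=lambda a: a.end)
    if right.end <= left.start:
        raise MissingAnchorError(f"anchors inverted on {rec.id}")
    start, end = left.start, right.end
    size = end - start
    L = rec.length
    if location_mode == "midpoint":
        loc = 100.0 * ((start + end) / 2.0) / L
    elif location_mode == "start":
        loc = 100.0 * start / L
    else:
        raise ValueError(f"unknown location_mode {location_mode!r}")
    inside = [
        a.gene_symbol
        for a in rec.annotations
        if a.gene_symbol and a.start >= start and a.end <= end
    ]
    return OriginIslandResult(
        replicon_id=rec.id,
        oric_pos=oric,
        island=(start, end),
        size=size,
        pct_of_chromosome=100.0 * size / L,
        location_pct=loc,
        gene_order=tuple(inside),
    )


def pars_statistics(
    hits: Sequence[ParSHit],
    oric: int,
    island: tuple[int, int],
    length: int,
) -> ParSStats:
    """Left/right and island/bulk distribution of parS hits.

    A hit with start <= oriC counts as left, start > oriC as right (the
    fixed convention: a site starting exactly at oriC is left).  Island
    membership is by start within [island_start, island_end).  Mean gaps are
    successive-start differences within a compartment and need >= 2 sites.
    """
    n = len(hits)
    if n == 0:
        return ParSStats(0, None, None, None, None, None)
    starts = sorted(h.start for h in hits)
    n_left = sum(1 for s in starts if s <= oric)
    pct_left = 100.0 * n_left / n
    a, b = island
    in_island = [s for s in starts if a <= s < b]
    in_bulk = [s for s in starts if not (a <= s < b)]
    pct_in_island = 100.0 * len(in_island) / n

    def mean_gap(xs: list[int]) -> Optional[float]:
        if len(xs) < 2:
            return None
        return float(sum(y - x for x, y in zip(xs, xs[1:])) / (len(xs) - 1))

    return ParSStats(
        n_sites=n,
        pct_left=pct_left,
        pct_right=100.0 - pct_left,
        pct_in_island=pct_in_island,
        mean_gap_island=mean_gap(in_island),
        mean_gap_bulk=mean_gap(in_bulk),
    )


_METRICS = (
    ("length", lambda r: r.length),
    ("tir_perfect", lambda r: r.tir_perfect),
    ("tir_imperfect", lambda r: r.tir_imperfect),
    ("island_size", lambda r: r.island.size if r.island else None),
    ("island_pct_of_chromosome",
     lambda r: r.island.pct_of_chromosome if r.island else None),
    ("island_location_pct", lambda r: r.island.location_pct if r.island else None),
    ("n_pars", lambda r: r.pars.n_sites if r.pars else None),
    ("pct_left", lambda r: r.pars.pct_left if r.pars else None),
    ("pct_right", lambda r: r.pars.pct_right if r.pars else None),
    ("pct_in_island", lambda r: r.pars.pct_in_island if r.pars else None),
    ("mean_gap_island", lambda r: r.pars.mean_gap_island if r.pars else None),
    ("mean_gap_bulk", lambda r: r.pars.mean_gap_bulk if r.pars else None),
)


def _aggregate(summaries: Sequence[RepliconSummary]):
    means: dict[str, float] = {}
    ranges: dict[str, tuple[float, float]] = {}
    for name, getter in _METRICS:
        vals = [getter(s) for s in summaries]
        vals = [v for v in vals if v is not None]
        if not vals:
            continue
        means[name] = float(sum(vals) / len(vals))
        ranges[name] = (float(min(vals)), float(max(vals)))
    return means, ranges


def summarize_cohort(summaries: Sequence[RepliconSummary]) -> CohortSummary:
    """Arithmetic means and min-max ranges across analysed replicons.

    Chromosomes and plasmids are aggregated separately; metrics missing on a
    replicon are excluded from that metric's mean rather than zero-filled.
    """
    if not summaries:
        raise ValueError("no replicons to summarize")
    oriented = {s.oriented for s in summaries}
    if len(oriented) > 1:
        raise ValueError("mixed oriented/unoriented replicons in cohort")
    chroms = [s for s in summaries if s.kind == "chromosome"]
    plasmids = [s for s in summaries if s.kind == "plasmid"]
    means, ranges = _aggregate(chroms) if chroms else ({}, {})
    pmeans, pranges = _aggregate(plasmids) if plasmids else ({}, {})
    return CohortSummary(
        n_chromosomes=len(chroms),
        n_plasmids=len(plasmids),
        means=means,
        ranges=ranges,
        plasmid_means=pmeans,
        plasmid_ranges=pranges,
    )
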