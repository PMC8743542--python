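"""Canonical orientation of linear replicons.

All cross-genome statistics (left/right replichore, parS bias, island
location) depend on every replicon pointing the same way.  The convention:
dnaN and dnaA are transcribed from the bottom strand (annotated '-') and
parA and parB from the top strand ('+').  Each marker present votes for
keeping or flipping the replicon; a majority decides, with dnaA breaking
ties.  When a marker gene has several copies, the copy nearest the replicon
midpoint is the voter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .records import RepliconRecord, Strand, require_linear

__all__ = ["OrientationDecision", "decide_orientation", "apply_orientation", "orient"]

log = logging.getLogger(__name__)

#: marker -> strand it must occupy after orientation
CANONICAL_STRANDS = {
    "dnaa": Strand.MINUS,
    "dnan": Strand.MINUS,
    "para": Strand.PLUS,
    "parb": Strand.PLUS,
}


class UnorientableError(ValueError):
    pass


@dataclass(frozen=True)
class OrientationDecision:
    """Outcome of the marker vote for one replicon."""

    replicon_id: str
    length: int
    flipped: bool
    evidence: dict[str, str]  # marker -> observed strand symbol
    votes: dict[str, bool]  # marker -> voted flip?
    confidence: tuple[int, int]  # (concordant markers, markers found)


def decide_orientation(rec: RepliconRecord, strict: bool = True) -> OrientationDecision:
    """Vote on whether ``rec`` must be reverse-complemented.

    dnaA/dnaN vote "flip" when found on '+'; parA/parB vote "flip" when on
    '-'.  Majority wins; on a tie dnaA's vote decides (dnaA anchors oriC, so
    its strand is the least negotiable).  With no marker at all the replicon
    is unorientable: an error in strict mode, otherwise passed through
    unflipped with a warning (plasmids without parAB and dnaA exist).
    """
    require_linear(rec, "orientation")
    evidence: dict[str, str] = {}
    votes: dict[str, bool] = {}
    for marker, canon in CANONICAL_STRANDS.items():
        ann = rec.feature_nearest_midpoint(marker)
        if ann is None:
            continue
        evidence[marker] = ann.strand.value
        votes[marker] = ann.strand is not canon
    if not votes:
        if strict:
            raise UnorientableError(f"unorientable replicon {rec.id}: "
                                    "none of dnaA/dnaN/parA/parB annotated")
        log.warning("replicon %s has no orientation markers; left unflipped", rec.id)
        return OrientationDecision(rec.id, rec.length, False, {}, {}, (0, 0))
    n_flip = sum(votes.values())
    n_keep = len(votes) - n_flip
    if n_flip > n_keep:
        flipped = True
    elif n_flip < n_keep:
        flipped = False
    else:
        flipped = votes.get("dnaa", False)
    concordant = sum(1 for v in votes.values() if v == flipped)
    return OrientationDecision(
        rec.id, rec.length, flipped, evidence, votes, (concordant, len(votes))
    )


def apply_orientation(rec: RepliconRecord, decision: OrientationDecision) -> RepliconRecord:
    """Apply a decision: reverse-complement and remap annotations, or identity.

    Applying the same decision twice returns the original record (the flip
    is an involution).
    """
    if decision.replicon_id != rec.id or decision.length != rec.length:
        raise ValueError(
            f"orientation decision for {decision.replicon_id} "
            f"({decision.length} bp) does not match record {rec.id} ({rec.length} bp)"
        )
    if not decision.flipped:
        return rec
    return rec.reverse_complemented()


def orient(rec: RepliconRecord, strict: bool = True) -> tuple[RepliconRecord, OrientationDecision]:
    """Decide and apply in one step."""
    d = decide_orientation(rec, strict=strict)
    return apply_orientation(rec, d), d
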