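"""Terminal inverted repeat (TIR) measurement.

A linear replicon's two ends often carry the same sequence in inverted
orientation: position k from the left end pairs with position k from the
right end.  The perfect TIR is the longest prefix that equals the reverse
complement of the equally long suffix; the imperfect TIR extends past the
perfect core allowing mismatches, using an ungapped X-drop extension with an
identity floor.  Both are capped at floor(L/2) so the two halves never
overlap, and any N breaks perfect extension (and counts as a mismatch in the
imperfect extension).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import RepliconRecord, require_linear

__all__ = ["TIRResult", "perfect_tir", "imperfect_tir"]

# base byte -> complement code; N (and anything else) maps to a code that
# never equals any plain-base code, so N vs anything is a mismatch.
_CODE = np.full(256, 5, dtype=np.int8)
for b, c in zip(b"ACGT", (0, 1, 2, 3)):
    _CODE[b] = c
_COMP = np.full(256, 6, dtype=np.int8)
for b, c in zip(b"ACGT", (3, 2, 1, 0)):
    _COMP[b] = c


@dataclass(frozen=True)
class TIRResult:
    replicon_id: str
    perfect_len: int
    imperfect_len: int
    imperfect_identity: float  # percent over the imperfect span (100.0 if equal)
    left_interval: tuple[int, int]
    right_interval: tuple[int, int]


def _end_match_mask(rec: RepliconRecord) -> np.ndarray:
    """mask[k] is True iff base k (from the left) pairs with base k from the
    right, i.e. prefix position k equals the complement of suffix position k."""
    half = rec.length // 2
    raw = np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)
    left = _CODE[raw[:half]]
    right = _COMP[raw[rec.length - half:][::-1]]
    return left == right


def perfect_tir(rec: RepliconRecord) -> int:
    """Length of the longest perfect terminal inverted repeat, in bp."""
    require_linear(rec, "TIRs")
    if rec.length < 2:
        raise ValueError("replicon too short for TIR measurement")
    mask = _end_match_mask(rec)
    if mask.all():
        return mask.size
    return int(np.argmin(mask))


def imperfect_tir(
    rec: RepliconRecord,
    min_identity: float = 90.0,
    xdrop: float = 50.0,
    match: float = 1.0,
    mismatch: float = -2.0,
) -> TIRResult:
    """Measure perfect and imperfect TIRs.

    From the perfect core the comparison of prefix vs reverse-complemented
    suffix is extended without gaps; extension stops when the running score
    drops more than ``xdrop`` below its maximum, and the imperfect extent is
    the position of that running maximum.  If identity over the extent falls
    below ``min_identity`` percent, the imperfect length falls back to the
    perfect length.
    """
    require_linear(rec, "TIRs")
    if rec.length < 2:
        raise ValueError("replicon too short for TIR measurement")
    mask = _end_match_mask(rec)
    perfect = mask.size if mask.all() else int(np.argmin(mask))

    steps = np.where(mask, match, mismatch)
    run = np.cumsum(steps)
    peak = np.maximum.accumulate(run)
    dropped = run < peak - xdrop
    stop = int(np.argmax(dropped)) if dropped.any() else mask.size
    if stop == 0:
        best = 0
    else:
        best = int(np.argmax(run[:stop])) + 1
        if run[best - 1] <= 0:  # no net terminal similarity
            best = 0
    imperfect = max(best, perfect)
    if imperfect > perfect:
        ident = 100.0 * float(np.count_nonzero(mask[:imperfect])) / imperfect
        if ident < min_identity:
            imperfect = perfect
            ident = 100.0
    else:
        ident = 100.0
    L = rec.length
    return TIRResult(
        replicon_id=rec.id,
        perfect_len=perfect,
        imperfect_len=imperfect,
        imperfect_identity=ident,
        left_interval=(0, imperfect),
        right_interval=(L - imperfect, L),
    )
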