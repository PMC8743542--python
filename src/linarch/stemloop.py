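"""Stem-loop (hairpin) prediction for telomeric DNA ends.

Streptomycete telomeres are 3' single-stranded overhangs that fold back on
themselves into series of short stems with 3-4 nt hairpins.  This module
finds the minimum-free-energy nested secondary structure of a DNA end under
a locality constraint: paired bases may be at most ``dmax`` nucleotides
apart (default 20), which restricts folding to the short-range palindromes
that characterise telomeres and keeps every loop inside a small window.

The energy model is deliberately reduced: Watson-Crick (+ optional G.T
wobble) pairs, nearest-neighbor stacking free energies read from a data
file, and a single Jacobson-Stockmeyer logarithmic penalty A + B*ln(n) for
every loop of n unpaired nucleotides (hairpin, bulge, interior and
multibranch alike).  Exterior unpaired bases are free.  Because pair spans
are bounded by ``dmax``, the interior of any closing pair is at most
``dmax - 1`` nt, and the dynamic programme can afford to track the exact
number of unpaired bases in each loop - so the logarithmic multibranch
penalty is exact, not linearised.

Reported free energies are comparable between sequences folded under the
same configuration but are not literature Delta-G values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Optional

__all__ = [
    "FoldConfig",
    "StemLoopStructure",
    "fold_end",
    "score_structure",
    "hairpin_census",
    "dot_bracket",
]

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


def _load_stack_table() -> tuple[dict[str, float], float]:
    table: dict[str, float] = {}
    wobble = -1.5
    text = resources.files("linarch.data").joinpath("stack_dna_synthetic.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, key, val = line.split("\t")
        if kind == "NN":
            table[key] = float(val)
        elif kind == "WOBBLE":
            wobble = float(val)
    return table, wobble


_STACKS, _WOBBLE_STACK = _load_stack_table()


@dataclass(frozen=True)
class FoldConfig:
    """Folding parameters.

    ``temperature_c`` and ``salt_m`` are carried as run metadata only; the
    shipped stack table is not rescaled by them.
    """

    dmax: int = 20
    min_hairpin: int = 3
    loop_a: float = 10.0  # kJ/mol, loop initiation
    loop_b: float = 4.41  # kJ/mol, ~1.75*R*T at 30 C
    # G.T wobble is off by default: a wobble pair has no image under
    # reverse complementation (G.T maps to A.C), so allowing it breaks the
    # strand-symmetry of delta_g that the rest of the pipeline relies on.
    allow_wobble: bool = False
    temperature_c: float = 30.0
    salt_m: float = 0.05
    stack_table: Optional[dict[str, float]] = None
    wobble_stack: float = _WOBBLE_STACK

    def __post_init__(self) -> None:
        if self.dmax < self.min_hairpin + 2:
            raise ValueError("dmax must be at least min_hairpin + 2")
        if self.loop_b <= 0:
            raise ValueError("loop_b must be positive")
        stacks = self.stack_table if self.stack_table is not None else _STACKS
        if any(v > 0 for v in stacks.values()):
            raise ValueError("stacking energies must be <= 0")

    def pairable(self, x: str, y: str) -> bool:
        if (x, y) in _WC:
            return True
        return self.allow_wobble and (x, y) in _WOBBLE

    def stack_energy(self, seq: str, i: int, j: int) -> float:
        """Energy of stacking pair (i, j) on pair (i+1, j-1)."""
        outer_wobble = (seq[i], seq[j]) in _WOBBLE
        inner_wobble = (seq[i + 1], seq[j - 1]) in _WOBBLE
        if outer_wobble or inner_wobble:
            return self.wobble_stack
        stacks = self.stack_table if self.stack_table is not None else _STACKS
        return stacks[seq[i] + seq[i + 1]]

    def loop_penalty(self, n_unpaired: int) -> float:
        if n_unpaired <= 0:
            return self.loop_a
        return self.loop_a + self.loop_b * math.log(n_unpaired)


@dataclass(frozen=True)
class StemLoopStructure:
    """A nested secondary structure of a DNA end."""

    sequence: str
    pairs: tuple[tuple[int, int], ...]  # sorted, i < j
    delta_g: float  # kJ/mol, <= 0; 0 for the empty structure
    stems: tuple[tuple[int, int, int, int], ...] = field(default=())
    # each stem: (first_i, first_j, n_pairs, _) covering pairs
    # (first_i+k, first_j-k) for k < n_pairs
    hairpin_loops: tuple[tuple[str, int], ...] = field(default=())
    # (loop sequence, 0-based start of the loop)

    @property
    def dotbracket(self) -> str:
        return dot_bracket(len(self.sequence), self.pairs)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def dot_bracket(n: int, pairs: Iterable[tuple[int, int]]) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


# DP values are (energy, n_pairs, pairs_tuple): minimising the tuple
# implements the tie-breaks "fewer pairs, then lexicographically earliest
# pair set" without a second pass.
_EMPTY = (0.0, 0, ())


def _add(a, b):
    return (a[0] + b[0], a[1] + b[1], tuple(sorted(a[2] + b[2])))


def _validate_sequence(seq: str, cfg: FoldConfig) -> None:
    if set(seq) - set("ACGT"):
        raise ValueError(
            "fold_end requires an unambiguous A/C/G/T sequence "
            f"(got characters {sorted(set(seq) - set('ACGT'))})"
        )
    if len(seq) < cfg.min_hairpin + 2:
        raise ValueError("sequence too short to fold")


def _mfe(seq: str, cfg: FoldConfig):
    """Exact MFE over nested structures with pair span <= dmax."""
    n = len(seq)
    V: dict[tuple[int, int], tuple] = {}

    @lru_cache(maxsize=None)
    def branch_dp(a: int, b: int):
        """Best coverage of interval [a, b] by unpaired bases and complete
        branches; returns {(n_unpaired, min(n_branches, 2)): value}."""
        out: dict[tuple[int, int], tuple] = {(0, 0): _EMPTY} if a > b else {}
        if a > b:
            return out
        # leave position a unpaired
        for (u, nb), val in branch_dp(a + 1, b).items():
            key = (u + 1, nb)
            if key not in out or val < out[key]:
                out[key] = val
        # open a branch at a
        for q in range(a + cfg.min_hairpin + 1, min(b, a + cfg.dmax) + 1):
            v = V.get((a, q))
            if v is None:
                continue
            for (u, nb), val in branch_dp(q + 1, b).items():
                cand = _add(v, val)
                key = (u, min(nb + 1, 2))
                if key not in out or cand < out[key]:
                    out[key] = cand
        return out

    # pairs in increasing span order so inner V values exist when needed
    for span in range(cfg.min_hairpin + 1, cfg.dmax + 1):
        for i in range(0, n - span):
            j = i + span
            if not cfg.pairable(seq[i], seq[j]):
                continue
            best = None
            for (u, nb), val in branch_dp(i + 1, j - 1).items():
                if nb == 0:
                    e = cfg.loop_penalty(u)  # hairpin; u >= min_hairpin
                elif nb == 1 and u == 0:
                    e = cfg.stack_energy(seq, i, j)  # stacked helix step
                else:
                    e = cfg.loop_penalty(u)  # bulge/interior/multibranch
                cand = _add((e, 1, ((i, j),)), val)
                if best is None or cand < best:
                    best = cand
            if best is not None:
                V[(i, j)] = best
        branch_dp.cache_clear()  # V grew; cached interior results are stale

    # exterior: unpaired bases free, any number of components
    W: list[tuple] = [_EMPTY] * (n + 1)
    for k in range(1, n + 1):
        best = W[k - 1]
        for i in range(max(0, k - 1 - cfg.dmax), k - 1):
            v = V.get((i, k - 1))
            if v is None:
                continue
            cand = _add(W[i], v)
            if cand < best:
                best = cand
        W[k] = best
    return W[n]


def _annotate(seq: str, pairs: tuple[tuple[int, int], ...]):
    """Derive stems (maximal runs of stacked pairs) and hairpin loops."""
    pairset = set(pairs)
    stems: list[tuple[int, int, int, int]] = []
    seen: set[tuple[int, int]] = set()
    for i, j in pairs:
        if (i, j) in seen:
            continue
        if (i - 1, j + 1) in pairset:
            continue  # not the outermost pair of its stem
        k = 0
        while (i + k, j - k) in pairset:
            seen.add((i + k, j - k))
            k += 1
        stems.append((i, j, k, 0))
    hairpins: list[tuple[str, int]] = []
    for i, j in pairs:
        if not any(i < a and b < j for a, b in pairs if (a, b) != (i, j)):
            hairpins.append((seq[i + 1:j], i + 1))
    return tuple(stems), tuple(sorted(hairpins, key=lambda t: t[1]))


def fold_end(seq: str, cfg: FoldConfig | None = None) -> StemLoopStructure:
    """Fold a DNA end (<= ~200 nt) into its minimum-free-energy structure.

    Returns the empty structure (delta_g = 0) when no negative-energy
    structure exists.  Ties are broken toward fewer pairs, then the
    lexicographically earliest pair set.
    """
    cfg = cfg or FoldConfig()
    seq = seq.upper()
    _validate_sequence(seq, cfg)
    energy, _, pairs = _mfe(seq, cfg)
    if energy >= 0:
        return StemLoopStructure(sequence=seq, pairs=(), delta_g=0.0)
    stems, hairpins = _annotate(seq, pairs)
    return StemLoopStructure(
        sequence=seq,
        pairs=pairs,
        delta_g=float(energy),
        stems=stems,
        hairpin_loops=hairpins,
    )


def score_structure(
    seq: str, pairs: Iterable[tuple[int, int]], cfg: FoldConfig | None = None
) -> float:
    """Free energy of an explicit pair set under the same model as fold_end.

    Used as the scoring half of the exhaustive-enumeration cross-check; it
    walks the loop decomposition directly instead of running the DP.
    """
    cfg = cfg or FoldConfig()
    seq = seq.upper()
    plist = sorted(pairs)
    pairset = set(plist)
    for i, j in plist:
        if not (0 <= i < j < len(seq)):
            raise ValueError(f"pair {(i, j)} out of range")
        if j - i > cfg.dmax or j - i - 1 < cfg.min_hairpin:
            raise ValueError(f"pair {(i, j)} violates span constraints")
        if not cfg.pairable(seq[i], seq[j]):
            raise ValueError(f"pair {(i, j)} not pairable: {seq[i]}.{seq[j]}")
    for (i, j) in plist:
        for (k, l) in plist:
            if i < k < j < l:
                raise ValueError("pseudoknotted pair set")
    used = [0] * len(seq)
    for i, j in plist:
        used[i] += 1
        used[j] += 1
    if any(u > 1 for u in used):
        raise ValueError("a base participates in more than one pair")

    total = 0.0
    for i, j in plist:
        children = [
            (a, b)
            for a, b in plist
            if i < a and b < j
            and not any(i < c < a and b < d < j for c, d in plist)
        ]
        interior = j - i - 1
        unpaired = interior - sum(b - a + 1 for a, b in children)
        if not children:
            total += cfg.loop_penalty(interior)
        elif len(children) == 1 and unpaired == 0:
            total += cfg.stack_energy(seq, i, j)
        else:
            total += cfg.loop_penalty(unpaired)
    return total


def hairpin_census(structs: Iterable[StemLoopStructure]):
    """Count hairpin-loop sequences across structures, sorted descending.

    Returns a list of (loop sequence, count); telomere panels dominated by
    GAA/GGA/GTA tri-loops reproduce the familiar census.
    """
    counts: dict[str, int] = {}
    for s in structs:
        for loop, _pos in s.hairpin_loops:
            counts[loop] = counts.get(loop, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
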