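"""parS site scanning with a log-odds weight matrix.

ParB loads onto the chromosome at short quasi-palindromic parS sites.  The
scanner builds a position weight matrix from aligned training sites with
background-proportional pseudocounts,

    W(b, i) = log2( ((counts(b, i) + k * p(b)) / (N + k)) / p(b) ),

and slides it over both strands of a replicon, keeping windows whose weight
score strictly exceeds the threshold (default > 15).  A palindromic site
scoring on both strands of the same window is reported once, keeping the
higher-scoring strand.

The packaged training counts (``data/pars_counts_synthetic.txt``) are a
synthetic stand-in built around the bacterial parS consensus
TGTTTCACGTGAAACA with self-reverse-complement-symmetric degeneracy; swap in
your own count table to scan with a different motif model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .records import RepliconRecord, reverse_complement

__all__ = [
    "WeightMatrix",
    "ParSHit",
    "build_matrix",
    "read_counts",
    "write_counts",
    "load_default_matrix",
    "genome_background",
    "scan",
    "UNIFORM_BACKGROUND",
]

log = logging.getLogger(__name__)

_BASES = "ACGT"
_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMP_IDX = np.array([3, 2, 1, 0])

UNIFORM_BACKGROUND = {b: 0.25 for b in _BASES}

_NEG = -1e9  # sentinel weight for N-containing windows


@dataclass(frozen=True)
class ParSHit:
    replicon_id: str
    start: int  # 0-based
    strand: str
    site: str  # genome subsequence, reverse-complemented for '-'
    score: float


class WeightMatrix:
    """Log2-odds weight matrix with background-proportional pseudocounts."""

    def __init__(
        self,
        counts: np.ndarray,  # shape (4, width), rows A,C,G,T
        background: dict[str, float],
        pseudocount: float = 1.0,
        name: str = "matrix",
    ):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x width array (rows A,C,G,T)")
        bg = np.array([background[b] for b in _BASES], dtype=float)
        if np.any(bg <= 0):
            raise ValueError("background probabilities must all be positive")
        bg = bg / bg.sum()
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        n_sites = counts.sum(axis=0)
        if not np.allclose(n_sites, n_sites[0]):
            raise ValueError("column count totals differ; sites unequal widths?")
        self.counts = counts
        self.n_sites = float(n_sites[0])
        self.background = {b: float(p) for b, p in zip(_BASES, bg)}
        self.pseudocount = float(pseudocount)
        self.name = name
        corrected = (counts + pseudocount * bg[:, None]) / (self.n_sites + pseudocount)
        self.frequencies = corrected  # columns sum to 1
        self.weights = np.log2(corrected / bg[:, None])

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.weights.argmax(axis=0))

    def score(self, site: str) -> float:
        """Weight score of one site of matrix width; N scores -inf."""
        site = site.upper()
        if len(site) != self.width:
            raise ValueError(f"site length {len(site)} != width {self.width}")
        total = 0.0
        for i, b in enumerate(site):
            if b not in _INDEX:
                return float("-inf")
            total += float(self.weights[_INDEX[b], i])
        return total

    def sample_site(self, rng: np.random.Generator) -> str:
        """Draw a site base-per-position from the corrected frequencies."""
        cols = [
            rng.choice(4, p=self.frequencies[:, i] / self.frequencies[:, i].sum())
            for i in range(self.width)
        ]
        return "".join(_BASES[c] for c in cols)


def build_matrix(
    sites: Sequence[str],
    background: Optional[dict[str, float]] = None,
    pseudocount: float = 1.0,
    name: str = "matrix",
) -> WeightMatrix:
    """Build a weight matrix from aligned, equal-width training sites.

    Columns that contain a gap character in any site are dropped (with a
    warning); remaining widths must agree.
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 training sites")
    sites = [s.upper() for s in sites]
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("training sites must have equal widths")
    gapped = {i for s in sites for i, c in enumerate(s) if c == "-"}
    if gapped:
        log.warning("dropping %d gapped alignment columns", len(gapped))
        sites = [
            "".join(c for i, c in enumerate(s) if i not in gapped) for s in sites
        ]
        width = len(sites[0])
    counts = np.zeros((4, width))
    for s in sites:
        for i, c in enumerate(s):
            if c not in _INDEX:
                raise ValueError(f"non-ACGT character {c!r} in training site")
            counts[_INDEX[c], i] += 1
    return WeightMatrix(counts, background or UNIFORM_BACKGROUND, pseudocount, name)


def genome_background(rec: RepliconRecord) -> dict[str, float]:
    """Mononucleotide frequencies of a replicon (N ignored)."""
    raw = np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)
    total = 0
    freqs = {}
    for b in _BASES:
        n = int((raw == ord(b)).sum())
        freqs[b] = n
        total += n
    if total == 0:
        raise ValueError("replicon has no unambiguous bases")
    return {b: n / total for b, n in freqs.items()}


def read_counts(path: Optional[str] = None) -> tuple[np.ndarray, str]:
    """Read a TRANSFAC-style position count table.

    Expected rows: a ``PO``/``P0`` header naming column order A C G T, then
    one numbered row of four counts per motif position.  Returns (counts as
    a 4 x width array in A,C,G,T row order, matrix name).
    """
    if path is None:
        text = resources.files("linarch.data").joinpath(
            "pars_counts_synthetic.txt"
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    name = "matrix"
    order: list[str] = []
    rows: list[list[float]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "XX", "//")):
            continue
        fields = line.split()
        tag = fields[0].upper()
        if tag == "ID":
            name = fields[1]
        elif tag in ("PO", "P0"):
            order = [f.upper() for f in fields[1:5]]
        elif tag[0].isdigit():
            rows.append([float(f) for f in fields[1:5]])
    if not rows:
        raise ValueError(f"no count rows found in matrix file")
    if not order:
        order = list(_BASES)
    arr = np.array(rows).T  # rows now in file base order
    counts = np.zeros_like(arr)
    for row, base in zip(arr, order):
        counts[_INDEX[base]] = row
    return counts, name


def write_counts(wm: WeightMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"ID {wm.name}\nPO A C G T\n")
        for i in range(wm.width):
            vals = " ".join(f"{wm.counts[_INDEX[b], i]:g}" for b in _BASES)
            fh.write(f"{i + 1:02d} {vals}\n")
        fh.write("XX\n")


def load_default_matrix(
    background: Optional[dict[str, float]] = None, pseudocount: float = 1.0
) -> WeightMatrix:
    """The packaged synthetic parS count table as a ready-to-scan matrix."""
    counts, name = read_counts(None)
    return WeightMatrix(counts, background or UNIFORM_BACKGROUND, pseudocount, name)


def _window_scores(code: np.ndarray, weights_ext: np.ndarray) -> np.ndarray:
    """Scores of all windows: weights_ext has shape (5, width); row 4 = N."""
    width = weights_ext.shape[1]
    n_win = code.size - width + 1
    scores = np.zeros(n_win)
    for i in range(width):
        scores += weights_ext[code[i:i + n_win], i]
    return scores


def scan(
    rec: RepliconRecord,
    wm: WeightMatrix,
    threshold: float = 15.0,
) -> list[ParSHit]:
    """Scan both strands for windows with weight score strictly > threshold.

    Windows containing N never match.  When the same window passes on both
    strands (a palindromic site), one hit is kept on the higher-scoring
    strand ('+' on an exact tie).  Hits are sorted by start.
    """
    if rec.length < wm.width:
        raise ValueError("replicon shorter than matrix width")
    if threshold >= wm.max_score:
        log.warning(
            "threshold %.3g unattainable (max score %.3g); no hits possible",
            threshold,
            wm.max_score,
        )
        return []
    raw = np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)
    code = np.full(raw.size, 4, dtype=np.int64)
    for b, i in _INDEX.items():
        code[raw == ord(b)] = i

    ext = np.vstack([wm.weights, np.full(wm.width, _NEG)])
    fwd = _window_scores(code, ext)
    # minus strand: score of revcomp(window) under W equals scoring the
    # forward window under W_rc(b, i) = W(comp(b), width-1-i)
    rc = np.vstack([wm.weights[_COMP_IDX, ::-1], np.full(wm.width, _NEG)])
    rev = _window_scores(code, rc)

    hits: list[ParSHit] = []
    idx = np.nonzero((fwd > threshold) | (rev > threshold))[0]
    # strand ties (palindromic sites) resolve to '+'; the tolerance absorbs
    # summation-order noise between the forward and rearranged reverse pass
    tol = 1e-9
    for s in idx:
        f, r = float(fwd[s]), float(rev[s])
        window = rec.sequence[s:s + wm.width]
        if f > threshold and (f >= r - tol or r <= threshold):
            hits.append(ParSHit(rec.id, int(s), "+", window, f))
        else:
            hits.append(ParSHit(rec.id, int(s), "-", reverse_complement(window), r))
    return hits
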