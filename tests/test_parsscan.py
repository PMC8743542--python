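"""Weight-matrix construction and parS scanning vs the naive per-window
scorer."""

import math

import numpy as np
import pytest

from linarch.parsscan import (
    UNIFORM_BACKGROUND,
    WeightMatrix,
    build_matrix,
    genome_background,
    load_default_matrix,
    read_counts,
    scan,
    write_counts,
)
from linarch.records import RepliconRecord, reverse_complement


def test_hand_computed_weights_and_score():
    """Frozen hand evaluation of the log-odds formula on a 4-site toy set:
    W(A,1) = log2(((4 + 0.25)/5)/0.25) = 1.765...; score(ACGT) = 6.674..."""
    wm = build_matrix(["ACGT", "ACGT", "ACGA", "ACGT"], UNIFORM_BACKGROUND, 1.0)
    assert wm.weights[0, 0] == pytest.approx(math.log2((4.25 / 5) / 0.25))
    assert wm.weights[0, 0] == pytest.approx(1.77, abs=0.01)
    expected = 3 * math.log2((4.25 / 5) / 0.25) + math.log2((3.25 / 5) / 0.25)
    assert wm.score("ACGT") == pytest.approx(expected)
    assert wm.score("ACGT") == pytest.approx(6.68, abs=0.01)


def test_equal_counts_and_vanishing_pseudocount_give_zero_weights():
    wm = build_matrix(["AC", "CA", "GG", "TT", "AT", "CG", "GC", "TA"],
                      UNIFORM_BACKGROUND, pseudocount=1e-12)
    assert np.allclose(wm.weights, 0.0, atol=1e-9)


def test_corrected_frequencies_sum_to_one():
    wm = load_default_matrix()
    assert np.allclose(wm.frequencies.sum(axis=0), 1.0)


def test_consensus_scores_max_score():
    wm = load_default_matrix({"A": 0.14, "C": 0.36, "G": 0.36, "T": 0.14})
    assert wm.score(wm.consensus) == pytest.approx(wm.max_score)
    assert wm.min_score <= 0 < wm.max_score


def test_gapped_columns_dropped():
    wm = build_matrix(["A-CG", "A-CG", "A-TG"], UNIFORM_BACKGROUND)
    assert wm.width == 3


def test_zero_background_rejected():
    with pytest.raises(ValueError):
        build_matrix(["ACGT", "ACGT"], {"A": 0.5, "C": 0.5, "G": 0.0, "T": 0.0})


def test_counts_round_trip(tmp_path):
    wm = load_default_matrix()
    path = str(tmp_path / "m.txt")
    write_counts(wm, path)
    counts, name = read_counts(path)
    assert np.allclose(counts, wm.counts)
    assert name == wm.name


def naive_scan(rec, wm, threshold):
    """Per-window reference scorer: score every window on both strands via
    WeightMatrix.score, then apply the strict threshold and palindrome
    merge by hand."""
    hits = []
    for s in range(rec.length - wm.width + 1):
        window = rec.sequence[s:s + wm.width]
        f = wm.score(window)
        r = wm.score(reverse_complement(window))
        if f > threshold and (f >= r or r <= threshold):
            hits.append((s, "+", f))
        elif r > threshold:
            hits.append((s, "-", r))
    return hits


def _rand_rec(rng, n, gc=0.72):
    seq = "".join(
        rng.choice(list("ACGT"), size=n, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    )
    return RepliconRecord(id="r", sequence=seq)


def test_scan_agrees_with_naive_oracle(rng, default_matrix):
    wm = default_matrix
    for trial in range(25):
        rec = _rand_rec(rng, int(rng.integers(500, 4000)))
        # plant a couple of sampled sites so hits exist
        seq = list(rec.sequence)
        for pos in (100, 700):
            site = wm.sample_site(rng)
            if trial % 2:
                site = reverse_complement(site)
            seq[pos:pos + wm.width] = site
        rec = RepliconRecord(id="r", sequence="".join(seq))
        got = [(h.start, h.strand, h.score) for h in scan(rec, wm, 15.0)]
        expected = naive_scan(rec, wm, 15.0)
        assert [(s, st) for s, st, _ in got] == [(s, st) for s, st, _ in expected]
        for (_, _, a), (_, _, b) in zip(got, expected):
            assert a == pytest.approx(b, abs=1e-9)


def test_planted_site_found_at_exact_position(rng, default_matrix):
    wm = default_matrix
    spurious = 0
    for trial in range(100):
        rec = _rand_rec(rng, 10_000)
        seq = list(rec.sequence)
        seq[4000:4000 + wm.width] = wm.consensus
        rec = RepliconRecord(id="r", sequence="".join(seq))
        hits = scan(rec, wm, 15.0)
        assert any(h.start == 4000 for h in hits)
        spurious += sum(1 for h in hits if h.start != 4000)
    assert spurious <= 2  # ~2e-9 per window keeps 2M windows nearly clean


def _asymmetric_matrix():
    """A deliberately non-palindromic motif so the two strands of a window
    score differently (the packaged parS matrix is palindrome-symmetric,
    which makes every hit a strand tie)."""
    sites = ["TTTTGGGGAAAACCCC"] * 8 + ["TTTAGGGGAAAACCCC", "TTTTGGGGAAAACCCG"]
    return build_matrix(sites, UNIFORM_BACKGROUND)


def test_minus_strand_site_reported_on_minus(rng):
    wm = _asymmetric_matrix()
    rec = _rand_rec(rng, 2000, gc=0.5)
    seq = list(rec.sequence)
    seq[500:500 + wm.width] = reverse_complement(wm.consensus)
    rec = RepliconRecord(id="r", sequence="".join(seq))
    hits = [h for h in scan(rec, wm, 15.0) if h.start == 500]
    assert len(hits) == 1
    h = hits[0]
    assert h.strand == "-"
    assert h.site == reverse_complement(rec.sequence[500:500 + wm.width])
    assert h.score == pytest.approx(wm.max_score)


def test_palindromic_double_hit_merged_to_single(default_matrix, rng):
    """The packaged motif is self-reverse-complementary: one planted
    consensus must yield exactly one hit, not a +/- pair."""
    wm = default_matrix
    rec = _rand_rec(rng, 2000)
    seq = list(rec.sequence)
    seq[800:800 + wm.width] = wm.consensus
    rec = RepliconRecord(id="r", sequence="".join(seq))
    hits = [h for h in scan(rec, wm, 15.0) if h.start == 800]
    assert len(hits) == 1 and hits[0].strand == "+"


def test_strand_symmetry_of_scan(rng):
    wm = _asymmetric_matrix()
    rec = _rand_rec(rng, 3000, gc=0.5)
    seq = list(rec.sequence)
    seq[1000:1000 + wm.width] = wm.consensus
    seq[2000:2000 + wm.width] = reverse_complement(wm.consensus)
    rec = RepliconRecord(id="r", sequence="".join(seq))
    fwd = scan(rec, wm, 15.0)
    rev = scan(RepliconRecord(id="r", sequence=reverse_complement(rec.sequence)), wm, 15.0)
    L = rec.length
    mirrored = sorted(
        (L - h.start - wm.width, {"+": "-", "-": "+"}[h.strand]) for h in rev
    )
    assert sorted((h.start, h.strand) for h in fwd) == mirrored


def test_hit_count_non_increasing_in_threshold(default_matrix, rng):
    wm = default_matrix
    rec = _rand_rec(rng, 20_000)
    seq = list(rec.sequence)
    for pos in range(1000, 15_000, 1000):
        seq[pos:pos + wm.width] = wm.sample_site(rng)
    rec = RepliconRecord(id="r", sequence="".join(seq))
    counts = [len(scan(rec, wm, t)) for t in (5, 10, 15, 20)]
    assert counts == sorted(counts, reverse=True)


def test_window_with_n_never_matches(default_matrix):
    wm = default_matrix
    seq = wm.consensus[:8] + "N" + wm.consensus[9:]
    rec = RepliconRecord(id="r", sequence="A" * 100 + seq + "A" * 100)
    assert scan(rec, wm, 0.0) == [] or all(
        "N" not in h.site for h in scan(rec, wm, 0.0)
    )


def test_unattainable_threshold_returns_empty(default_matrix, rng):
    wm = default_matrix
    rec = _rand_rec(rng, 1000)
    assert scan(rec, wm, wm.max_score + 1) == []


def test_genome_background_reflects_composition():
    rec = RepliconRecord(id="r", sequence="GGGCCCCCGA")
    bg = genome_background(rec)
    assert bg["C"] == pytest.approx(0.5)
    assert bg["G"] == pytest.approx(0.4)
    assert sum(bg.values()) == pytest.approx(1.0)
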