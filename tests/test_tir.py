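"""Terminal inverted repeat measurement against an exhaustive oracle."""

import pytest

from linarch.records import RepliconRecord, reverse_complement
from linarch.tir import imperfect_tir, perfect_tir


def oracle_perfect(seq):
    """Longest k <= L//2 with prefix(k) == revcomp(suffix(k)), checked
    base-by-base — deliberately naive."""
    r = reverse_complement(seq)
    best = 0
    for k in range(len(seq) // 2):
        a, b = seq[k], r[k]
        if a != b or a == "N":
            break
        best = k + 1
    return best


def _rand(rng, n, gc=0.72):
    return "".join(
        rng.choice(list("ACGT"), size=n, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    )


def _plant(rng, tirlen, total):
    """Sequence with an exact planted perfect TIR of tirlen bp."""
    core = _rand(rng, total - 2 * tirlen)
    block = _rand(rng, tirlen)
    seq = block + core + reverse_complement(block)
    # guarantee divergence just past the TIR
    lst = list(seq)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if tirlen < len(seq) // 2 and lst[tirlen] == comp[lst[-tirlen - 1]]:
        lst[tirlen] = {"A": "C", "C": "A", "G": "T", "T": "G"}[lst[tirlen]]
    return "".join(lst)


def test_planted_tir_recovered_exactly(rng):
    seq = _plant(rng, 20, 400)
    assert perfect_tir(RepliconRecord(id="p", sequence=seq)) == 20


def test_non_complementary_termini_give_zero():
    rec = RepliconRecord(id="z", sequence="AAAA" + "GCGC" * 10 + "AAAA")
    assert perfect_tir(rec) == 0  # A...A termini: A pairs T, not A


def test_circular_replicon_rejected():
    rec = RepliconRecord(id="c", sequence="ACGT" * 10, topology="circular")
    with pytest.raises(ValueError):
        perfect_tir(rec)


def test_palindromic_sequence_caps_at_half():
    block = "ACGTTGCA" * 8
    seq = block + reverse_complement(block)
    assert perfect_tir(RepliconRecord(id="pal", sequence=seq)) == len(seq) // 2


def test_perfect_matches_oracle_on_random_and_planted(rng):
    for trial in range(300):
        n = int(rng.integers(50, 2000))
        if trial % 2:
            seq = _plant(rng, int(rng.integers(0, n // 3)), n)
        else:
            seq = _rand(rng, n)
        rec = RepliconRecord(id=f"t{trial}", sequence=seq)
        assert perfect_tir(rec) == oracle_perfect(seq)


def test_perfect_symmetric_under_reverse_complement(rng):
    for trial in range(50):
        seq = _plant(rng, int(rng.integers(5, 50)), 500)
        rec = RepliconRecord(id="s", sequence=seq)
        rc = RepliconRecord(id="s", sequence=reverse_complement(seq))
        assert perfect_tir(rec) == perfect_tir(rc)


def test_extension_monotone_under_planting(rng):
    base = _plant(rng, 30, 600)
    rec = RepliconRecord(id="m", sequence=base)
    k = perfect_tir(rec)
    ext = _rand(rng, 7)
    grown = ext + base + reverse_complement(ext)
    assert perfect_tir(RepliconRecord(id="m2", sequence=grown)) == k + 7


def test_n_breaks_perfect_extension():
    block = "ACGTACGTAC"
    seq = block + "N" + "TTTT" * 20 + "N" + reverse_complement(block)
    assert perfect_tir(RepliconRecord(id="n", sequence=seq)) == len(block)


def oracle_imperfect(seq, xdrop=50.0, match=1.0, mismatch=-2.0):
    """Best-scoring ungapped extent by evaluating every k directly."""
    r = reverse_complement(seq)
    best_k, best_score, run = 0, 0.0, 0.0
    peak = 0.0
    for k in range(len(seq) // 2):
        ok = seq[k] == r[k] and seq[k] != "N"
        run += match if ok else mismatch
        peak = max(peak, run)
        if run < peak - xdrop:
            break
        if run > best_score:
            best_score, best_k = run, k + 1
    return best_k if best_score > 0 else 0


def test_imperfect_extends_past_perfect_core(rng):
    """20 bp perfect core + 80 bp at ~95% identity, then divergence."""
    core = _rand(rng, 20)
    ext = list(_rand(rng, 80))
    seq_mid = _rand(rng, 200)
    right_ext = [c for c in reverse_complement("".join(ext))]
    # plant 4 scattered mismatches in the right-hand copy of the extension;
    # the first sits at the extension start so the perfect core stays 20 bp
    for pos in (0, 30, 50, 70):
        j = 80 - 1 - pos
        right_ext[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[right_ext[j]]
    seq = core + "".join(ext) + seq_mid + "".join(right_ext) + reverse_complement(core)
    rec = RepliconRecord(id="imp", sequence=seq)
    res = imperfect_tir(rec)
    assert res.perfect_len == 20
    assert res.imperfect_len == 100
    assert res.imperfect_identity == pytest.approx(96.0)
    assert res.left_interval == (0, 100)
    assert res.right_interval == (rec.length - 100, rec.length)


def test_fully_perfect_tir_degenerates(rng):
    seq = _plant(rng, 50, 500)
    res = imperfect_tir(RepliconRecord(id="d", sequence=seq))
    assert res.perfect_len == 50
    assert res.imperfect_len >= 50
    if res.imperfect_len == 50:
        assert res.imperfect_identity == 100.0


def test_no_terminal_similarity_gives_zero(rng):
    # non-palindromic random interior; A...A termini mismatch immediately
    rec = RepliconRecord(id="z", sequence="AAAA" + _rand(rng, 100) + "AAAA")
    res = imperfect_tir(rec)
    assert res.imperfect_len == 0 and res.perfect_len == 0


def test_imperfect_matches_extent_oracle(rng):
    for trial in range(100):
        n = int(rng.integers(100, 1500))
        seq = _plant(rng, int(rng.integers(0, n // 4)), n)
        # sprinkle mutations near the ends to create imperfect structure
        lst = list(seq)
        for _ in range(int(rng.integers(0, 10))):
            i = int(rng.integers(0, n // 3))
            lst[i] = "ACGT"[int(rng.integers(0, 4))]
        seq = "".join(lst)
        rec = RepliconRecord(id=f"x{trial}", sequence=seq)
        res = imperfect_tir(rec, min_identity=0.0)
        assert max(res.perfect_len, oracle_imperfect(seq)) == res.imperfect_len
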