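"""Aligner oracles: hand-built rearrangements, DP identity oracle, PAF I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asmcompare.alignkit import (AlignmentBlock, anchor_chain_align,
                                 pairwise_identity, read_paf, write_paf)
from asmcompare.seqio import Assembly, revcomp


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return bytes(rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n))


def _asm(name, **chroms):
    return Assembly({k: v for k, v in chroms.items()}, name=name)


def test_identical_chromosomes_single_full_block():
    seq = _random_seq(10_000, 1)
    blocks = anchor_chain_align(_asm("a", chr1=seq), _asm("b", chr1=seq), k=21)
    assert len(blocks) == 1
    b = blocks[0]
    assert (b.query_start, b.query_end) == (0, 10_000)
    assert (b.target_start, b.target_end) == (0, 10_000)
    assert b.strand == "+" and b.identity == 1.0


def test_interior_deletion_splits_into_adjacent_blocks():
    # seed chosen so the junction bases differ on both sides and block
    # boundaries land exactly on the deletion breakpoints
    seq = _random_seq(12_000, 3)
    assert seq[5000] != seq[7000] and seq[4999] != seq[6999]
    b_seq = seq[:5000] + seq[7000:]          # 2 kb interior deletion
    blocks = anchor_chain_align(_asm("a", chr1=seq), _asm("b", chr1=b_seq), k=21)
    assert len(blocks) == 2
    left, right = sorted(blocks, key=lambda b: b.query_start)
    # verified by direct string search of the flanks
    assert b_seq.find(seq[:5000]) == 0
    assert b_seq.find(seq[7000:]) == 5000
    assert left.query_end == 5000 and right.query_start == 7000
    assert left.target_end == right.target_start == 5000


def test_interior_inversion_yields_minus_middle_block():
    seq = _random_seq(12_000, 3)
    b_seq = seq[:5000] + revcomp(seq[5000:8000]) + seq[8000:]
    blocks = anchor_chain_align(_asm("a", chr1=seq), _asm("b", chr1=b_seq), k=21)
    assert len(blocks) == 3
    blocks.sort(key=lambda b: b.query_start)
    assert [b.strand for b in blocks] == ["+", "-", "+"]
    mid = blocks[1]
    assert (mid.query_start, mid.query_end) == (5000, 8000)
    assert (mid.target_start, mid.target_end) == (5000, 8000)


def test_k_larger_than_shortest_chromosome_rejected():
    with pytest.raises(ValueError, match="exceeds"):
        anchor_chain_align(_asm("a", c=_random_seq(50, 4)),
                           _asm("b", c=_random_seq(50, 4)), k=60)
    with pytest.raises(ValueError, match="k must be"):
        anchor_chain_align(_asm("a", c=_random_seq(50, 4)),
                           _asm("b", c=_random_seq(50, 4)), k=5)


_ROTATE = {65: 67, 67: 71, 71: 84, 84: 65}  # A->C->G->T->A, never silent


def test_block_identity_reproducible_from_sequences():
    rng = np.random.default_rng(5)
    a = _random_seq(8000, 6)
    mutated = bytearray(a)
    for pos in rng.choice(8000, size=8, replace=False):
        mutated[pos] = _ROTATE[mutated[pos]]
    b = bytes(mutated)
    blocks = anchor_chain_align(_asm("a", c=a), _asm("b", c=b), k=21,
                                min_block=1000)
    assert blocks
    for blk in blocks:
        span_a = a[blk.query_start:blk.query_end]
        span_b = b[blk.target_start:blk.target_end]
        n = min(len(span_a), len(span_b))
        matches = sum(x == y for x, y in zip(span_a[:n], span_b[:n]))
        assert matches == blk.matches


# ---------------------------------------------------------------------------
# pairwise identity


def test_identity_trivial_cases():
    assert pairwise_identity(b"A" * 100, b"A" * 100) == 1.0
    s = _random_seq(100, 7)
    t = bytearray(s)
    t[50] = ord("A") if s[50] != ord("A") else ord("C")
    assert pairwise_identity(s, bytes(t)) == pytest.approx(0.99)


def test_identity_known_edit_script():
    """5 substitutions plus one 10 bp gap over 200 columns -> 185/200."""
    s1 = bytearray(_random_seq(190, 9))
    s2 = bytearray(s1)
    for pos in (10, 40, 80, 120, 160):
        s2[pos] = _ROTATE[s2[pos]]
    s2 = bytes(s2[:95]) + _random_seq(10, 10) + bytes(s2[95:])
    assert pairwise_identity(bytes(s1), s2) == pytest.approx(185 / 200)


def test_identity_symmetric_and_rejects_empty():
    s1, s2 = _random_seq(60, 11), _random_seq(55, 12)
    assert pairwise_identity(s1, s2) == pairwise_identity(s2, s1)
    with pytest.raises(ValueError):
        pairwise_identity(b"", s1)


def _edit_distance_dp(s1: bytes, s2: bytes) -> int:
    """Quadratic Needleman-Wunsch edit distance, the independent oracle."""
    n, m = len(s1), len(s2)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (s1[i - 1] != s2[j - 1]))
        prev = cur
    return prev[m]


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=50),
       st.text(alphabet="ACGT", min_size=1, max_size=50))
def test_identity_matches_dp_oracle(s1, s2):
    b1, b2 = s1.encode(), s2.encode()
    expected = 1.0 - _edit_distance_dp(b1, b2) / max(len(b1), len(b2))
    assert pairwise_identity(b1, b2) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# PAF I/O


def test_paf_round_trip(tmp_path):
    block = AlignmentBlock("chr1", 100, 5100, "chr2", 200, 5200, "-",
                           4987, 5000, tags={"tp": "A:P"})
    path = tmp_path / "x.paf"
    write_paf([block], path, {"chr1": 10_000}, {"chr2": 12_000})
    (back,) = read_paf(path)
    assert back == block


def test_paf_minus_strand_convention(tmp_path):
    path = tmp_path / "m.paf"
    path.write_text("q\t1000\t10\t900\t-\tt\t2000\t100\t990\t880\t890\t255\n")
    (b,) = read_paf(path)
    assert b.strand == "-"
    assert b.query_start == 10 and b.query_end == 900  # + strand coords per PAF


@pytest.mark.parametrize("line, message", [
    ("q\t1000\t10\t900\t+\tt\t2000\t100\n", "columns"),
    ("q\t1000\t900\t10\t+\tt\t2000\t100\t990\t880\t890\t255\n", "invalid"),
    ("q\t1000\tx\t900\t+\tt\t2000\t100\t990\t880\t890\t255\n", "malformed"),
])
def test_paf_malformed_lines_name_the_line(tmp_path, line, message):
    path = tmp_path / "bad.paf"
    path.write_text(line)
    with pytest.raises(ValueError, match=message):
        read_paf(path)
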