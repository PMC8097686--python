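"""k-mer coding, window profiles and window similarity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from longtr.kmers import (
    Read,
    encode_kmer,
    decode_kmer,
    error_free_kmer_prob,
    similarity,
    slide_profile,
    window_profile,
)

from conftest import random_seq

EXAMPLE_READ = Read("ex", "TCAGACACACACGGTC")


@pytest.mark.parametrize(
    "kmer,code",
    [("AAA", 0), ("ACG", 6), ("TT", 15), ("A", 0), ("T", 3), ("GATTACA", 9156)],
)
def test_encode_kmer_quaternary(kmer, code):
    assert encode_kmer(kmer) == code
    assert decode_kmer(code, len(kmer)) == kmer


def test_encode_kmer_rejects_bad_input():
    with pytest.raises(ValueError, match="offset 2"):
        encode_kmer("ACNZ")
    with pytest.raises(ValueError):
        encode_kmer("")


@pytest.mark.parametrize(
    "i,expected",
    [(0, (1, 1, 1, 1)), (4, (2, 2, 0, 0)), (8, (2, 2, 0, 0)), (12, (0, 1, 2, 1))],
)
def test_window_profile_worked_example(i, expected):
    """1-mer frequency vectors of the four length-4 windows of
    TCAGACACACACGGTC."""
    p = window_profile(EXAMPLE_READ, i, 4, 1)
    assert tuple(p.counts) == expected


def test_window_profile_homopolymer():
    assert tuple(window_profile(Read("h", "AAAA"), 0, 4, 1).counts) == (4, 0, 0, 0)


def test_window_profile_count_conservation(rng):
    for _ in range(20):
        n = int(rng.integers(10, 80))
        read = Read("r", random_seq(rng, n))
        k = int(rng.integers(1, 5))
        w = int(rng.integers(k, min(n, 20) + 1))
        i = int(rng.integers(0, n - w + 1))
        p = window_profile(read, i, w, k)
        assert p.counts.sum() == w - k + 1
        assert (p.counts >= 0).all()


def test_window_profile_rejects_out_of_range():
    with pytest.raises(ValueError):
        window_profile(EXAMPLE_READ, 14, 4, 1)
    with pytest.raises(ValueError):
        window_profile(EXAMPLE_READ, -1, 4, 1)


def test_slide_profile_matches_from_scratch(rng):
    """Incremental slide equals a recomputed profile at every position."""
    for _ in range(10):
        n = int(rng.integers(12, 60))
        read = Read("r", random_seq(rng, n))
        k = int(rng.integers(1, 4))
        w = int(rng.integers(k, 12))
        if w > n - 1:
            continue
        p = window_profile(read, 0, w, k)
        for i in range(1, n - w + 1):
            p = slide_profile(p, read)
            expect = window_profile(read, i, w, k)
            assert np.array_equal(p.counts, expect.counts)
        with pytest.raises(ValueError):
            slide_profile(p, read)


def test_slide_profile_first_step_example():
    p = slide_profile(window_profile(EXAMPLE_READ, 0, 4, 1), EXAMPLE_READ)
    assert tuple(p.counts) == (2, 1, 1, 0)  # window CAGA


def test_slide_profile_homopolymer_constant():
    read = Read("h", "A" * 30)
    p = window_profile(read, 0, 8, 2)
    for _ in range(10):
        p = slide_profile(p, read)
        assert p.counts[0] == 7 and p.counts.sum() == 7


@pytest.mark.parametrize(
    "i,j,expected",
    [(8, 12, 0.25), (0, 4, 0.5), (4, 8, 1.0)],
)
def test_manhattan_similarity_worked_example(i, j, expected):
    """S(8,12) < S(0,4) < S(4,8) with the printed values 0.25, 0.5, 1."""
    p = window_profile(EXAMPLE_READ, i, 4, 1)
    q = window_profile(EXAMPLE_READ, j, 4, 1)
    assert similarity(p, q, "manhattan") == pytest.approx(expected, abs=1e-12)


def test_pearson_anticorrelation_and_midpoint():
    p = window_profile(Read("a", "ACACGTGT"), 0, 4, 1)  # (2,2,0,0)
    q = window_profile(Read("a", "ACACGTGT"), 4, 4, 1)  # (0,0,2,2)
    assert similarity(p, q, "pearson") == pytest.approx(0.0, abs=1e-12)
    # zero-variance profile (all counts equal): defined midpoint, not an error
    flat = window_profile(Read("f", "ACGTACGT"), 0, 4, 1)  # (1,1,1,1)
    assert similarity(flat, flat, "pearson") == 0.5


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1), st.integers(1, 3), st.integers(4, 12))
def test_similarity_properties(seed, k, w):
    """Both measures are symmetric, bounded in [0,1], and reach 1 on
    identical profiles (pearson: when variance is positive)."""
    rng = np.random.default_rng(seed)
    read = Read("r", random_seq(rng, 3 * w))
    p = window_profile(read, 0, w, k)
    q = window_profile(read, w, w, k)
    for m in ("manhattan", "pearson"):
        s_pq = similarity(p, q, m)
        assert 0.0 <= s_pq <= 1.0
        assert s_pq == pytest.approx(similarity(q, p, m))
    assert similarity(p, p, "manhattan") == 1.0
    if np.var(p.counts) > 0:
        assert similarity(p, p, "pearson") == pytest.approx(1.0)


def test_similarity_requires_matching_shape():
    p = window_profile(EXAMPLE_READ, 0, 4, 1)
    q = window_profile(EXAMPLE_READ, 0, 5, 1)
    with pytest.raises(ValueError):
        similarity(p, q)


def test_error_free_kmer_prob_declines_with_k():
    # at a 20% error rate: 80, 64, 51.2, 41.0, 32.8, 26.2 percent
    expected = [0.8, 0.64, 0.512, 0.4096, 0.32768, 0.262144]
    got = [error_free_kmer_prob(0.2, k) for k in range(1, 7)]
    assert got == pytest.approx(expected)


def test_read_validation():
    with pytest.raises(ValueError):
        Read("bad", "ACGTN")
    with pytest.raises(ValueError):
        Read("empty", "")
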