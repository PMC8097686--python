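"""Wraparound alignment against brute-force oracles, LCS similarity,
and split points."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from longtr.align import lcs_similarity, split_point, suffix_sigma, wraparound_align

from conftest import random_seq


def brute_force_delta(unit: str, region: str) -> int:
    """Minimum Levenshtein distance of the region to any substring of an
    unbounded tandem concatenation of the unit, by explicit enumeration:
    every rotation times every prefix length, via a full DP whose last
    row holds the distances to all target prefixes."""
    best = None
    tlen = len(region) + 2 * len(unit)
    for r in range(len(unit)):
        rot = unit[r:] + unit[:r]
        target = (rot * (tlen // len(unit) + 1))[:tlen]
        prev = np.arange(len(region) + 1)
        row_best = prev[-1]
        for ch in target:
            cur = np.empty_like(prev)
            cur[0] = 0  # a shorter target prefix is just a later rotation start
            for i in range(1, len(region) + 1):
                cur[i] = min(
                    prev[i - 1] + (region[i - 1] != ch),
                    prev[i] + 1,
                    cur[i - 1] + 1,
                )
            prev = cur
            row_best = min(row_best, prev[-1])
        best = row_best if best is None else min(best, row_best)
    return int(best)


@pytest.mark.parametrize(
    "unit,region,sigma,delta,copies",
    [
        ("ACG", "ACGACGACGACG", 12, 0, 4.0),
        ("ACG", "ACAACGACGGCG", 10, 2, None),  # two substitutions
        ("A", "AAAAA", 5, 0, 5.0),
    ],
)
def test_wraparound_known_cases(unit, region, sigma, delta, copies):
    res = wraparound_align(unit, region)
    assert res.sigma == sigma
    assert res.delta == delta
    assert res.sigma == len(region) - res.delta
    if copies is not None:
        assert res.copies == pytest.approx(copies)


def test_wraparound_equals_brute_force(rng):
    """sigma from the DP equals the enumeration oracle on random pairs."""
    for _ in range(60):
        u = random_seq(rng, int(rng.integers(1, 9)))
        m = int(rng.integers(1, 41))
        region = random_seq(rng, m)
        res = wraparound_align(u, region)
        assert res.delta == brute_force_delta(u, region), (u, region)


def test_wraparound_rotation_invariance(rng):
    """With a free starting phase, sigma is identical for every rotation
    of the unit."""
    for _ in range(10):
        u = random_seq(rng, int(rng.integers(2, 10)))
        region = random_seq(rng, 50)
        sigmas = {
            wraparound_align(u[r:] + u[:r], region).sigma for r in range(len(u))
        }
        assert len(sigmas) == 1


def test_prefix_sigma_consistency(rng):
    """prefix_sigma[x] equals a from-scratch alignment of the prefix."""
    u = random_seq(rng, 6)
    region = random_seq(rng, 60)
    res = wraparound_align(u, region)
    assert res.prefix_sigma[0] == 0
    assert res.prefix_sigma[-1] == res.sigma
    for x in rng.integers(1, len(region) + 1, 20):
        assert res.prefix_sigma[x] == wraparound_align(u, region[: int(x)]).sigma


def test_suffix_sigma_consistency(rng):
    u = random_seq(rng, 5)
    region = random_seq(rng, 40)
    suf = suffix_sigma(u, region)
    for x in (0, 1, 7, 20, len(region)):
        if x == 0:
            assert suf[0] == 0
        else:
            assert suf[x] == wraparound_align(u, region[-x:]).sigma


def test_wraparound_identity_and_columns():
    res = wraparound_align("ACG", "ACGACGACGACG")
    assert res.identity == 1.0
    assert res.matches == 12 and res.columns == 12
    assert res.match_flags.all()


def test_wraparound_rejects_empty():
    with pytest.raises(ValueError):
        wraparound_align("", "ACGT")
    with pytest.raises(ValueError):
        wraparound_align("ACG", "")


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("ACAACGACGGCG", "ACGACGACGACG", 10 / 12),
        ("ACAACGACG", "ACGACGACG", 8 / 9),
    ],
)
def test_lcs_similarity_worked_examples(a, b, expected):
    assert lcs_similarity(a, b) == pytest.approx(expected)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=20),
       st.text(alphabet="ACGT", min_size=1, max_size=20))
def test_lcs_similarity_properties(a, b):
    s = lcs_similarity(a, b)
    assert 0.0 <= s <= 1.0
    assert s == pytest.approx(lcs_similarity(b, a))
    assert lcs_similarity(a, a) == 1.0
    if len(a) == len(b) and a != b:
        assert s < 1.0


def _call_arrays(unit, read_seq, s, e):
    res = wraparound_align(unit, read_seq[s:e])
    return res.prefix_sigma, suffix_sigma(unit, read_seq[s:e])


def test_split_point_disjoint_returns_first_end(rng):
    read_seq = random_seq(rng, 100)
    pre_i, _ = _call_arrays("AC", read_seq, 0, 40)
    _, suf_j = _call_arrays("GT", read_seq, 60, 100)
    assert split_point(pre_i, 0, 40, suf_j, 60, 100) == 40


def test_split_point_abutting_perfect_repeats():
    """Two perfect repeats with overlapping calls split at the junction."""
    read_seq = "AC" * 30 + "GT" * 30
    s_i, e_i = 0, 63  # call i overruns by 3
    s_j, e_j = 57, 120  # call j starts early by 3
    pre_i, _ = _call_arrays("AC", read_seq, s_i, e_i)
    _, suf_j = _call_arrays("GT", read_seq, s_j, e_j)
    x = split_point(pre_i, s_i, e_i, suf_j, s_j, e_j)
    assert x == 60
    # exhaustive check of the objective
    o = lambda x: (
        wraparound_align("AC", read_seq[s_i:x]).sigma
        + wraparound_align("GT", read_seq[x:e_j]).sigma
    )
    assert all(o(x) >= o(y) for y in range(s_j, e_i + 1))


def test_split_point_overlap_owned_by_first_call():
    """When the overlap region continues the first unit, the split sits
    at the end of the first call."""
    read_seq = "AC" * 35 + "GAGTT" * 12
    s_i, e_i = 0, 70
    s_j, e_j = 64, 130
    pre_i, _ = _call_arrays("AC", read_seq, s_i, e_i)
    _, suf_j = _call_arrays("GAGTT", read_seq, s_j, e_j)
    x = split_point(pre_i, s_i, e_i, suf_j, s_j, e_j)
    assert x == e_i
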