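"""Boundary score arrays, the (k, w) grid, and candidate detection."""

import numpy as np
import pytest

from longtr.boundaries import (
    GridPattern,
    boundary_scores,
    detect_candidates,
    parameter_grid,
    scan_read,
)
from longtr.kmers import Read, similarity, window_profile
from longtr.simulate import BenchmarkSpec, ERROR_PRESETS, simulate_read

from conftest import random_seq


def test_parameter_grid_progressions():
    grid = parameter_grid()
    assert len(grid) == 20
    assert [p for p in grid if p.k == 5] == [GridPattern(5, 5 * 2**l) for l in range(12)]
    assert [p for p in grid if p.k == 3] == [GridPattern(3, 5 * 2**l) for l in range(5)]
    assert [p for p in grid if p.k == 1] == [GridPattern(1, 5 * 2**l) for l in range(3)]
    assert GridPattern(3, 80) in grid
    assert GridPattern(1, 40) not in grid


def test_boundary_scores_homopolymer_flat():
    read = Read("h", "A" * 200)
    for k, w in [(1, 5), (3, 10), (5, 20)]:
        B, E, _, _ = boundary_scores(read, w, k)
        assert np.allclose(B, 0.0) and np.allclose(E, 0.0)


def test_boundary_scores_definition_and_antisymmetry(rng):
    """B and E computed by the linear scan match their window-similarity
    definitions, and E(i, w) = -B(i-w, w) to machine precision."""
    for _ in range(5):
        n = int(rng.integers(60, 140))
        read = Read("r", random_seq(rng, n))
        for k, w in [(1, 5), (2, 8), (3, 10)]:
            if n < 3 * w + 1:
                continue
            for m in ("manhattan", "pearson"):
                B, E, b0, e0 = boundary_scores(read, w, k, m)
                S = lambda i, j: similarity(
                    window_profile(read, i, w, k), window_profile(read, j, w, k), m
                )
                for idx in range(0, len(B), 7):
                    i = b0 + idx
                    assert B[idx] == pytest.approx(S(i, i + w) - S(i - w, i), abs=1e-9)
                for idx in range(0, len(E), 7):
                    i = e0 + idx
                    assert E[idx] == pytest.approx(
                        S(i - 2 * w, i - w) - S(i - w, i), abs=1e-9
                    )
                # antisymmetry, elementwise over the whole valid range
                assert np.array_equal(E, -B)


def test_boundary_scores_short_read_empty():
    B, E, _, _ = boundary_scores(Read("s", "ACGTACGT"), 5, 1)
    assert len(B) == 0 and len(E) == 0


def test_peak_localizes_planted_repeat(rng):
    """argmax B lands within w of the planted repeat start."""
    flank = random_seq(rng, 500)
    read = Read("r", flank + "ACGTG" * 100 + random_seq(rng, 500))
    B, E, b0, _ = boundary_scores(read, 80, 3)
    assert abs((b0 + int(np.argmax(B))) - 500) <= 80


def test_detect_candidates_planted_repeat(rng):
    """One candidate, boundaries within w, for a 25-mer x 200 array under
    Nanopore-like errors at (k, w) = (5, 160)."""
    rt = simulate_read(
        BenchmarkSpec(unit_len=25, copies=200, error=ERROR_PRESETS["nanopore_like"]),
        rng,
    )
    cands = detect_candidates(rt.read, GridPattern(5, 160))
    assert len(cands) >= 1
    assert any(abs(c.b - rt.true_start) <= 160 for c in cands)
    # every candidate lies inside the (w-fuzzy) repeat; e is only the
    # closest end-score maximum, so the full extent is recovered later
    # by alignment, not here
    for c in cands:
        assert c.e >= c.b + c.w
        assert c.b >= rt.true_start - c.w and c.b <= rt.true_end


def test_detect_candidates_random_read_large_windows(rng):
    """Large-window patterns stay silent on repeat-free sequence."""
    read = Read("r", random_seq(rng, 4000))
    for pattern in [GridPattern(5, 160), GridPattern(5, 320), GridPattern(5, 640)]:
        cands = detect_candidates(read, pattern, theta_b=0.2, adaptive=False)
        assert cands == []


def test_window_much_larger_than_span_misses(rng):
    """A repeat of span L vanishes once windows dwarf it (w >> L/2):
    the repeat content is diluted inside every window."""
    flank = random_seq(rng, 4000)
    read = Read("r", flank + "ACGTG" * 80 + random_seq(rng, 4000))  # span 400
    cands = detect_candidates(read, GridPattern(5, 1280), adaptive=False)
    hits = [c for c in cands if c.b < 4400 and c.e > 4000]
    assert hits == []


def test_scan_read_empty_and_structure(rng):
    assert scan_read(Read("e", "A")) == []
    rt = simulate_read(
        BenchmarkSpec(unit_len=20, copies=100, error=ERROR_PRESETS["accurate"]), rng
    )
    cands = scan_read(rt.read)
    overlapping = [
        c for c in cands if c.e > rt.true_start and c.b < rt.true_end
    ]
    assert overlapping, "grid scan must produce candidates over the repeat"


def test_scan_read_four_planted_repeats(rng):
    """A read with four repeats of very different unit lengths yields at
    least one candidate overlapping each."""
    units = [random_seq(rng, n) for n in (4, 20, 50, 150)]
    copies = [100, 40, 30, 12]
    parts = [random_seq(rng, 300)]
    spans = []
    pos = 300
    for u, c in zip(units, copies):
        arr = u * c
        spans.append((pos, pos + len(arr)))
        parts.append(arr)
        parts.append(random_seq(rng, 600))
        pos += len(arr) + 600
    read = Read("multi", "".join(parts))
    cands = scan_read(read)
    for lo, hi in spans:
        assert any(c.b < hi and c.e > lo for c in cands), (lo, hi)
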