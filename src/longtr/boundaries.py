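"""Candidate repeat ranges from k-mer window similarity peaks.

For a window size ``w``, ``B(i, w) = S(i, i+w) - S(i-w, i)`` peaks at the
start of a tandem repeat (the window to the right of ``i`` suddenly
resembles its right neighbor) and ``E(i, w) = -B(i-w, w)`` peaks at the
end.  A start ``b`` must locally maximize B within distance ``w`` and
clear a configurable floor ``theta_b``; the matching end is the closest
local maximum of E at least ``w`` to the right.  Detectability of a repeat
of unit u and span L at a pattern (k, w) requires roughly
``2|u| <= w <= L/2`` and ``k <= |u| < c * 4^k``; the fixed 20-pattern
geometric grid (k = 5, 3, 1 with w = 5 * 2^l) covers units up to ~500 nt
and spans up to ~10^5 nt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d

from ._kernels import window_similarity_scan
from .kmers import Read, SimilarityMeasure, kmer_codes, seq_to_digits

__all__ = [
    "GridPattern",
    "CandidateRange",
    "parameter_grid",
    "boundary_scores",
    "detect_candidates",
    "scan_read",
]

DEFAULT_THETA_B = 0.2


@dataclass(frozen=True)
class GridPattern:
    k: int
    w: int


@dataclass
class CandidateRange:
    """A putative tandem repeat interval from one (k, w) pattern."""

    read_id: str
    b: int
    e: int
    k: int
    w: int
    peak_b: float
    peak_e: float


def parameter_grid() -> list[GridPattern]:
    """The fixed 20-pattern (k, w) sampling grid.

    (5, 5*2^l) for l = 0..11, (3, 5*2^l) for l = 0..4 and (1, 5*2^l)
    for l = 0..2.
    """
    grid = [GridPattern(5, 5 * 2**l) for l in range(12)]
    grid += [GridPattern(3, 5 * 2**l) for l in range(5)]
    grid += [GridPattern(1, 5 * 2**l) for l in range(3)]
    return grid


def _similarity_scan(read: Read, w: int, k: int, measure: SimilarityMeasure) -> np.ndarray:
    n = len(read)
    if n < 2 * w or w < k:
        return np.empty(0, dtype=np.float64)
    codes = kmer_codes(seq_to_digits(read.seq), k)
    return window_similarity_scan(
        codes, n, w, k, 4**k, measure is SimilarityMeasure.PEARSON
    )


def boundary_scores(
    read: Read,
    w: int,
    k: int,
    measure: SimilarityMeasure | str = SimilarityMeasure.MANHATTAN,
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """B and E score arrays for one (k, w) pattern.

    Returns ``(B, E, b0, e0)`` where ``B[i]`` is B(b0 + i, w) for
    b0 = w (valid through |R| - 2w) and ``E[i]`` is E(e0 + i, w) for
    e0 = 2w (valid through |R| - w).  Both arrays are empty when the read
    is shorter than 3w.
    """
    measure = SimilarityMeasure(measure)
    S = _similarity_scan(read, w, k, measure)
    if len(S) <= w:
        empty = np.empty(0, dtype=np.float64)
        return empty, empty, w, 2 * w
    # S[i] = S(i, i+w); B(i) = S[i] - S[i-w]; E(i) = S[i-2w] - S[i-w]
    B = S[w:] - S[:-w]
    E = -B
    return B, E, w, 2 * w


def _local_maxima(scores: np.ndarray, radius: int) -> np.ndarray:
    """Boolean mask of positions that maximize ``scores`` within ``radius``."""
    if len(scores) == 0:
        return np.zeros(0, dtype=bool)
    return scores >= maximum_filter1d(scores, size=2 * radius + 1, mode="nearest")


MIN_THETA_B = 0.05
NOISE_Z = 4.0


def detect_candidates(
    read: Read,
    pattern: GridPattern,
    measure: SimilarityMeasure | str = SimilarityMeasure.MANHATTAN,
    theta_b: float = DEFAULT_THETA_B,
    adaptive: bool = True,
) -> list[CandidateRange]:
    """Candidate (b, e) ranges for one grid pattern.

    Starts are local maxima of B within distance w clearing the peak
    floor (leftmost position on ties); each start is paired with the
    closest end point e >= b + w that locally maximizes E within
    distance w.  After an (b, e) pair is emitted scanning resumes at e,
    so several repeats per read can be reported at the same pattern.

    ``theta_b`` is the ceiling of the floor.  B fluctuations shrink with
    the window size, and at high error rates the boundary peaks of long
    units are weak, so with ``adaptive`` the effective floor is lowered
    to ``NOISE_Z`` robust standard deviations of the B distribution when
    that is smaller (never below ``MIN_THETA_B``).
    """
    if theta_b < 0:
        raise ValueError("theta_b must be non-negative")
    k, w = pattern.k, pattern.w
    B, E, b0, e0 = boundary_scores(read, w, k, measure)
    if len(B) == 0:
        return []
    theta = theta_b
    if adaptive:
        sd = 1.4826 * float(np.median(np.abs(B - np.median(B))))
        theta = max(MIN_THETA_B, min(theta_b, NOISE_Z * sd))
    b_idx = np.nonzero(_local_maxima(B, w) & (B >= theta))[0]
    e_idx = np.nonzero(_local_maxima(E, w))[0]
    out: list[CandidateRange] = []
    n = len(read)
    pos = 0
    for i in b_idx:
        if i < pos:
            continue
        b = b0 + int(i)
        # closest end point with b + w <= e that locally maximizes E
        lo = max(b + w, e0) - e0
        jj = np.searchsorted(e_idx, lo)
        j = int(e_idx[jj]) if jj < len(e_idx) else len(E)
        if j < len(E):
            e, pe = e0 + j, float(E[j])
        else:  # no E peak right of b: the repeat runs to the end of the read
            e, pe = min(n, max(b + w, n - w)), float(E[-1])
        out.append(
            CandidateRange(
                read_id=read.id, b=b, e=e, k=k, w=w, peak_b=float(B[i]), peak_e=pe
            )
        )
        pos = max(i + 1, e - b0)
    return out


def scan_read(
    read: Read,
    measure: SimilarityMeasure | str = SimilarityMeasure.MANHATTAN,
    theta_b: float = DEFAULT_THETA_B,
    grid: list[GridPattern] | None = None,
) -> list[CandidateRange]:
    """Candidates over the whole parameter grid, concatenated.

    Overlapping candidates from different patterns are not merged here;
    downstream chaining resolves them.
    """
    if grid is None:
        grid = parameter_grid()
    out: list[CandidateRange] = []
    for pattern in grid:
        out.extend(detect_candidates(read, pattern, measure, theta_b))
    return out
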