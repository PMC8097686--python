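"""Wraparound alignment of a repeat unit against a read interval.

The unit ``u`` is treated as a cycle: the region ``R[s, e]`` is aligned
against an unbounded tandem concatenation of ``u`` with unit edit costs
(substitution = insertion = deletion = 1) and a free starting phase.  The
score reported is sigma = (e - s) - delta where delta is the optimal
Levenshtein distance, i.e. matches minus differences of the best alignment.

``prefix_sigma[x]`` holds sigma(u, R[s, s+x]) for every prefix of the
region, a by-product of the row-wise DP that the chaining stage uses to
place optimal split points between adjacent repeat calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import wraparound_dp, wraparound_traceback
from .kmers import seq_to_digits

__all__ = [
    "AlignmentResult",
    "wraparound_align",
    "lcs_similarity",
    "split_point",
]


@dataclass
class AlignmentResult:
    """Outcome of aligning a unit against a region of length ``m``."""

    sigma: int
    delta: int
    copies: float
    identity: float
    matches: int
    columns: int
    prefix_sigma: np.ndarray = field(repr=False)  # sigma over region prefixes, len m+1
    match_flags: np.ndarray = field(repr=False)  # per-region-base match indicator
    column_counts: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False
    )  # (nbase, delc, insc) multiple-alignment column statistics


def wraparound_align(
    unit: str, region: str, *, with_columns: bool = False
) -> AlignmentResult:
    """Optimal wraparound alignment of ``region`` to the cyclic ``unit``.

    ``copies`` is the number of unit characters traversed divided by the unit
    length (fractional terminal copies included); ``identity`` is matches
    over alignment columns.
    """
    if not unit:
        raise ValueError("empty unit")
    if not region:
        raise ValueError("empty region")
    r = seq_to_digits(region)
    u = seq_to_digits(unit)
    delta, end_j, ptr, rowmin = wraparound_dp(r, u)
    consumed, matches, columns, flags, nbase, delc, insc = wraparound_traceback(
        ptr, end_j, r, u
    )
    m = len(region)
    prefix_sigma = np.arange(m + 1, dtype=np.int64) - rowmin
    return AlignmentResult(
        sigma=int(m - delta),
        delta=int(delta),
        copies=float(consumed) / len(unit),
        identity=float(matches) / columns if columns else 0.0,
        matches=int(matches),
        columns=int(columns),
        prefix_sigma=prefix_sigma,
        match_flags=flags,
        column_counts=(nbase, delc, insc) if with_columns else None,
    )


def suffix_sigma(unit: str, region: str) -> np.ndarray:
    """``out[x]`` = sigma(u, region[len-x:]) for x = 0..len(region).

    Computed by aligning the reversed region against the reversed unit
    (reversal preserves wraparound edit distance up to rotation, and the
    starting phase is free)."""
    res = wraparound_align(unit[::-1], region[::-1])
    return res.prefix_sigma


def lcs_similarity(a: str, b: str) -> float:
    """Length of the longest common subsequence over the average length.

    The measure behind tau-similarity: two strings are tau-similar when
    this ratio is at least tau.
    """
    if not a or not b:
        raise ValueError("lcs_similarity requires non-empty strings")
    if len(a) < len(b):
        a, b = b, a
    prev = np.zeros(len(b) + 1, dtype=np.int64)
    for ca in a:
        cur = prev.copy()
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                v = prev[j - 1] + 1
                if v > cur[j]:
                    cur[j] = v
            if cur[j - 1] > cur[j]:
                cur[j] = cur[j - 1]
        prev = cur
    return float(prev[-1]) / ((len(a) + len(b)) / 2.0)


def split_point(
    prefix_sigma_i: np.ndarray,
    s_i: int,
    e_i: int,
    suffix_sigma_j: np.ndarray,
    s_j: int,
    e_j: int,
) -> int:
    """Optimal division point between two overlapping repeat calls.

    Maximizes o(x) = sigma(u_i, R[s_i, x]) + sigma(u_j, R[x, e_j]) over
    x in [s_j, e_i]; the smallest maximizing x is returned.  When the calls
    do not overlap the split is e_i.
    """
    if s_i >= s_j:
        raise ValueError("calls must be ordered by start")
    if e_i <= s_j:
        return e_i
    hi = min(e_i, e_j)  # a call swallowed whole can only be cut at its end
    xs = np.arange(s_j, hi + 1)
    o = prefix_sigma_i[xs - s_i] + suffix_sigma_j[e_j - xs]
    return int(xs[int(np.argmax(o))])
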