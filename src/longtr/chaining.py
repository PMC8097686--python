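"""Pseudo-disjoint chaining of candidate repeat calls.

Candidate calls from different (k, w) patterns overlap freely; the final
report keeps a maximum-total-score subset.  Two calls are treated as
compatible when their overlap is below a small limit l (default 10 nt),
which keeps the O(n log n) sorted-by-end chaining algorithm applicable.
Slightly overlapping survivors are then trimmed at the optimal split
point so the reported intervals are strictly disjoint.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .align import split_point, suffix_sigma, wraparound_align

__all__ = ["RepeatCall", "ChainConfig", "chain", "finalize", "dedup_calls"]


@dataclass
class RepeatCall:
    """A tandem repeat call T = (s, e, u, sigma) with report metadata."""

    read_id: str
    s: int
    e: int
    unit: str
    sigma: int
    copies: float = 0.0
    identity: float = 0.0
    k_used: int = 0
    w_used: int = 0
    prefix_sigma: np.ndarray | None = field(default=None, repr=False)
    suffix_sigma: np.ndarray | None = field(default=None, repr=False)

    @property
    def span(self) -> int:
        return self.e - self.s


@dataclass
class ChainConfig:
    overlap_limit: int = 10
    min_sigma_frac: float = 0.2
    min_span: int = 0

    def __post_init__(self) -> None:
        if self.overlap_limit < 0:
            raise ValueError("overlap_limit must be non-negative")


def dedup_calls(calls: list[RepeatCall]) -> list[RepeatCall]:
    """Keep the best-scoring call per identical interval."""
    best: dict[tuple[int, int], RepeatCall] = {}
    for c in calls:
        key = (c.s, c.e)
        if key not in best or c.sigma > best[key].sigma:
            best[key] = c
    return sorted(best.values(), key=lambda c: (c.s, c.e))


def chain(calls: list[RepeatCall], cfg: ChainConfig | None = None) -> list[RepeatCall]:
    """Maximum-weight pseudo-disjoint chain, in coordinate order.

    T_i may precede T_j when s_j >= e_i - l; chain weight is the sum of
    member sigma.  Calls failing the sigma or span floors are dropped
    before chaining, as are calls spanning no more than l itself: such a
    call fits inside a permitted overlap, which would let the end-sorted
    best-predecessor recursion chain a pair in the wrong start order.
    """
    cfg = cfg or ChainConfig()
    if not calls:
        return []
    if len({c.read_id for c in calls}) > 1:
        raise ValueError("chain() expects calls from a single read")
    kept = [
        c
        for c in calls
        if c.sigma >= cfg.min_sigma_frac * c.span
        and c.span >= cfg.min_span
        and c.span > cfg.overlap_limit
    ]
    kept = dedup_calls(kept)
    if not kept:
        return []
    kept.sort(key=lambda c: (c.e, c.s))
    ends = [c.e for c in kept]
    # best_to[i]: best chain weight among kept[0..i] ending with a call whose
    # end is <= ends[i]; prefix-max over the end-sorted order
    score = [0.0] * len(kept)
    parent = [-1] * len(kept)
    prefix_best = [0.0] * len(kept)
    prefix_arg = [-1] * len(kept)
    for i, c in enumerate(kept):
        # best predecessor: any call with e_p <= s_i + l
        hi = bisect.bisect_right(ends, c.s + cfg.overlap_limit, 0, i)
        prev_score, prev_idx = (prefix_best[hi - 1], prefix_arg[hi - 1]) if hi else (0.0, -1)
        score[i] = prev_score + c.sigma
        parent[i] = prev_idx
        if i == 0:
            prefix_best[i], prefix_arg[i] = score[i], i
        elif score[i] > prefix_best[i - 1]:
            prefix_best[i], prefix_arg[i] = score[i], i
        else:
            prefix_best[i], prefix_arg[i] = prefix_best[i - 1], prefix_arg[i - 1]
    i = int(np.argmax(score))
    out: list[RepeatCall] = []
    while i >= 0:
        out.append(kept[i])
        i = parent[i]
    out.reverse()
    return out


def _retrim(call: RepeatCall, read_seq: str) -> RepeatCall:
    """Recompute alignment numbers after an interval was trimmed."""
    region = read_seq[call.s : call.e]
    if not region or not call.unit:
        return call
    res = wraparound_align(call.unit, region)
    call.sigma = res.sigma
    call.copies = res.copies
    call.identity = res.identity
    call.prefix_sigma = res.prefix_sigma
    call.suffix_sigma = suffix_sigma(call.unit, region)
    return call


def finalize(calls: list[RepeatCall], read_seq: str) -> list[RepeatCall]:
    """Trim a chained list at optimal split points into disjoint records.

    For each slightly-overlapping adjacent pair the division point x*
    maximizing o(x) = sigma_i(prefix to x) + sigma_j(suffix from x) is
    taken from the stored prefix/suffix score arrays; both calls are then
    realigned on their trimmed intervals.
    """
    if not calls:
        return []
    calls = sorted(calls, key=lambda c: (c.s, c.e))
    out = [calls[0]]
    for nxt in calls[1:]:
        cur = out[-1]
        if nxt.s < cur.e:  # pseudo-disjoint overlap to resolve
            if nxt.s <= cur.s:  # co-started tiny overlap: cede it to cur
                x = min(cur.e, nxt.e)
            elif cur.prefix_sigma is None or nxt.suffix_sigma is None:
                x = cur.e if cur.e <= nxt.s else nxt.s
            else:
                x = split_point(
                    cur.prefix_sigma, cur.s, cur.e, nxt.suffix_sigma, nxt.s, nxt.e
                )
            cur.e = x
            nxt.s = x
            if cur.span > 0:
                _retrim(cur, read_seq)
            else:
                out.pop()
            if nxt.span <= 0:
                continue
            _retrim(nxt, read_seq)
        out.append(nxt)
    return [c for c in out if c.span > 0]
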