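"""Greedy consensus repeat unit from a k-mer de Bruijn graph.

In a candidate range with many unit copies, k-mers free of sequencing
error occur far more often than erroneous ones, so the consensus unit is
sought as a heavy cycle: starting from the most frequent k-mer, repeatedly
move to the successor set of maximal frequency, expanding the frontier
until it collapses to a singleton, dies out (failure), or reaches the
start vertex again (the cycle closes).  The procedure is run for each k in
a sweep (default 2..15), forward and, if the forward search fails,
backward over reversed edges; candidate units from different k compete by
their wraparound alignment score against the range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kmers import BASES, kmer_codes, seq_to_digits

__all__ = [
    "DeBruijnGraph",
    "UnitCandidate",
    "build_graph",
    "greedy_cycle",
    "CycleResult",
]

DEFAULT_K_RANGE = range(2, 16)


@dataclass
class DeBruijnGraph:
    """k-mer counts of a subsequence; edges v=bx -> z=xa are implicit."""

    k: int
    freq: dict[int, int] = field(repr=False)

    def count(self, code: int) -> int:
        return self.freq.get(code, 0)

    @property
    def total(self) -> int:
        return sum(self.freq.values())


@dataclass
class UnitCandidate:
    unit: str
    k_used: int
    cycle_weight: int
    sigma: int = 0


@dataclass
class CycleResult:
    digits: list[int]
    weight: int


def build_graph(seq: str, k: int) -> DeBruijnGraph:
    """k-mer frequency table of ``seq`` (a candidate range of a read)."""
    if len(seq) < k:
        raise ValueError(f"range of length {len(seq)} shorter than k={k}")
    codes = kmer_codes(seq_to_digits(seq), k)
    vals, counts = np.unique(codes, return_counts=True)
    return DeBruijnGraph(k=k, freq={int(v): int(c) for v, c in zip(vals, counts)})


def _expand_frontier(
    freq: dict[int, int], frontier: list[int], k: int, backward: bool
) -> tuple[list[int], dict[int, int]]:
    """One frontier step: all max-frequency neighbors of the frontier.

    Returns the new frontier (sorted, deduplicated) and a parent map
    choosing, for each new vertex, the predecessor of maximal frequency
    (ties: smallest k-mer code).
    """
    tail_mod = 4 ** (k - 1)
    best_f = 0
    neighbors: dict[int, int] = {}  # vertex -> best parent
    for v in frontier:
        for a in range(4):
            z = (v % tail_mod) * 4 + a if not backward else v // 4 + a * tail_mod
            f = freq.get(z, 0)
            if f == 0:
                continue
            if f > best_f:
                best_f = f
            if z not in neighbors:
                neighbors[z] = v
            else:
                p = neighbors[z]
                if (freq[v], -v) > (freq[p], -p):
                    neighbors[z] = v
    nxt = sorted(z for z in neighbors if freq[z] == best_f)
    return nxt, {z: neighbors[z] for z in nxt}


def greedy_cycle(
    g: DeBruijnGraph,
    kappa: int,
    *,
    backward: bool = False,
    max_len: int | None = None,
) -> CycleResult | None:
    """Heaviest-successor cycle through ``kappa``; None when the search fails.

    The frontier next(V) holds the maximum-frequency neighbors of V and is
    expanded until it is empty (failure), a singleton, or contains kappa
    (close the cycle).  The traversed edge path is recovered through parent
    pointers; edge labels concatenate to the unit.  ``max_len`` caps the
    cycle length (a unit longer than half the range cannot repeat in it);
    frontier expansion is capped likewise to guarantee termination.
    """
    freq = g.freq
    if kappa not in freq:
        raise ValueError("start k-mer absent from the graph")
    k = g.k
    cap = max_len if max_len is not None else 4**k
    digits: list[int] = []
    weight = freq[kappa]
    v = kappa
    while True:
        frontier = [v]
        levels: list[dict[int, int]] = []
        target = -1
        while True:
            nxt, parents = _expand_frontier(freq, frontier, k, backward)
            if not nxt:
                return None
            levels.append(parents)
            if kappa in nxt:
                target = kappa
                break
            if len(nxt) == 1:
                target = nxt[0]
                break
            if len(levels) + len(digits) > cap:
                return None
            frontier = nxt
        # backtrack the h edges from v to target
        path = [target]
        for parents in reversed(levels):
            path.append(parents[path[-1]])
        path.reverse()  # [v, ..., target]
        prev = path[0]
        for z in path[1:]:
            # forward, the label of an edge into z is the last character of
            # z; backward, the traversed edge is (z -> prev) in the original
            # orientation, labeled by the last character of prev
            digits.append(z % 4 if not backward else prev % 4)
            weight += freq[z]
            prev = z
        v = target
        if v == kappa:
            weight -= freq[kappa]  # start vertex counted once
            break
        if len(digits) > cap:
            return None
    if backward:
        digits.reverse()
    return CycleResult(digits=digits, weight=weight)


def candidate_units(
    seq: str,
    k_range: range | list[int] = DEFAULT_K_RANGE,
    *,
    max_starts: int = 4,
) -> list[UnitCandidate]:
    """One best greedy unit per k over the sweep, prior to scoring.

    For each k every maximally frequent k-mer (up to ``max_starts``, in
    code order) is tried as the start vertex; the heaviest successful
    cycle wins.  A forward failure triggers a backward search from the
    same start.  k values with no successful cycle are skipped.
    """
    out: list[UnitCandidate] = []
    max_len = max(1, len(seq) // 2)
    for k in k_range:
        if len(seq) < k + 1:
            continue
        g = build_graph(seq, k)
        top = max(g.freq.values())
        starts = sorted(c for c, f in g.freq.items() if f == top)[:max_starts]
        best: CycleResult | None = None
        for kappa in starts:
            for backward in (False, True):
                res = greedy_cycle(g, kappa, backward=backward, max_len=max_len)
                if res is not None and res.digits:
                    if best is None or res.weight > best.weight:
                        best = res
                    break  # backward only on forward failure
        if best is None or len(best.digits) > max_len:
            continue
        unit = "".join(BASES[d] for d in best.digits)
        out.append(UnitCandidate(unit=unit, k_used=k, cycle_weight=best.weight))
    return out


def canonical_rotation(u: str) -> str:
    """Lexicographically least rotation (Booth-style scan, O(n^2) is fine
    at unit scale); rotations of a unit are equivalent."""
    if not u:
        return u
    doubled = u + u
    return min(doubled[i : i + len(u)] for i in range(len(u)))
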