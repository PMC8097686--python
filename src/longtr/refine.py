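"""Error repair of a greedy consensus unit.

Two stages.  The first scans the k-mer frequencies along the (cyclic)
unit: a k-mer carrying a sequencing error is far rarer in the candidate
range than error-free k-mers, so a run of low-frequency k-mers marks a
suspect base.  Each suspect position is tested against the operation
table (no-op, 3 substitutions, 1 deletion, 4 insertions) and the edit
that maximizes the summed frequency of the covering k-mers is applied.

The second stage aligns the range back to the unit with wraparound DP,
collapses the unit copies into a multiple alignment, and tests every
column hypothesis (for each position: 3 substitutions, 1 deletion, 4
insertions = 8|u| hypotheses) with an exact binomial upper tail at
per-event probability eps/4, Bonferroni-corrected to 1%/(8|u|).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom

from .align import wraparound_align
from .assembly import DeBruijnGraph
from .kmers import BASES, encode_kmer

__all__ = [
    "column_tail",
    "bonferroni_alpha",
    "transition_repair",
    "ma_polish",
]

PASS_BUDGET = 5
LOW_FREQ_FRACTION = 0.5
MIN_MODAL_FREQ = 10


def column_tail(K: int, d: int, eps: float) -> float:
    """P(X >= K) for X ~ Binomial(d, eps/4): the chance that K or more of
    the d aligned unit copies show the same discrepancy by sequencing
    error alone."""
    if not 0 <= K <= d:
        raise ValueError(f"need 0 <= K <= d, got K={K}, d={d}")
    if not 0.0 <= eps < 1.0:
        raise ValueError("eps must be in [0, 1)")
    return float(binom.sf(K - 1, d, eps / 4.0))


def bonferroni_alpha(unit_len: int) -> float:
    """Significance level 1% split over the 8|u| column hypotheses."""
    if unit_len < 1:
        raise ValueError("unit_len must be positive")
    return 0.01 / (8.0 * unit_len)


def _cyclic_kmer(u: str, i: int, k: int) -> str:
    tiled = u * (k // len(u) + 2)
    return tiled[i : i + k]


def _window_score(u: str, center: int, k: int, freq: dict[int, int]) -> int:
    """Summed frequency of the k-mers starting at j = center-k+1 .. center
    of the cyclic unit."""
    n = len(u)
    total = 0
    for j in range(center - k + 1, center + 1):
        total += freq.get(encode_kmer(_cyclic_kmer(u, j % n, k)), 0)
    return total


def transition_repair(
    u: str,
    g: DeBruijnGraph,
    *,
    low_fraction: float = LOW_FREQ_FRACTION,
    min_modal: int = MIN_MODAL_FREQ,
    passes: int = PASS_BUDGET,
) -> str:
    """Repair single-base errors in ``u`` flagged by k-mer frequency dips.

    A position is suspect when every k-mer covering it has frequency below
    ``low_fraction`` times the median k-mer frequency along the unit.  The
    stage is skipped entirely when that median is below ``min_modal``:
    for low-copy repeats a rare k-mer may simply be correct.
    """
    k = g.k
    if not u:
        return u
    for _ in range(passes):
        n = len(u)
        freqs = np.array(
            [g.count(encode_kmer(_cyclic_kmer(u, i, k))) for i in range(n)]
        )
        med = float(np.median(freqs))
        if med < min_modal:
            return u
        low = freqs < low_fraction * med
        if not low.any() or low.all():
            return u
        # boundaries of maximal (cyclic) low runs: scanning the k-mer
        # frequencies forward, a run's last low start s1 pins the error
        # at base s1; scanning backward, the first low start s0 pins it
        # at base s0 + k - 1 (a deletion leaves only k-1 low k-mers, so
        # both boundaries are needed)
        suspects: set[int] = set()
        for s in range(n):
            if low[s] and not low[(s + 1) % n]:
                suspects.add(s)
            if low[s] and not low[(s - 1) % n]:
                suspects.add((s + k - 1) % n)
        best_gain, best_edit = 0, None
        for p in sorted(suspects):
            base_score = _window_score(u, p, k, g.freq)
            for op, a in [("sub", a) for a in BASES if a != u[p]] + [
                ("del", None)
            ] + [("ins", a) for a in BASES]:
                if op == "sub":
                    cand = u[:p] + a + u[p + 1 :]
                elif op == "del":
                    if n == 1:
                        continue
                    cand = u[:p] + u[p + 1 :]
                else:
                    cand = u[: p + 1] + a + u[p + 1 :]
                gain = _window_score(cand, min(p, len(cand) - 1), k, g.freq) - base_score
                if gain > best_gain:
                    best_gain, best_edit = gain, cand
        if best_edit is None:
            return u
        u = best_edit
    return u


def _column_edits(
    u: str,
    nbase: np.ndarray,
    delc: np.ndarray,
    insc: np.ndarray,
    eps: float,
) -> list[tuple[float, int, str, str]]:
    """Significant column edits as (p-value, position, op, base).

    An edit must both pass the Bonferroni-corrected tail test and be the
    column consensus (majority evidence), so that a significant minority
    at high depth never overrides a correct base.
    """
    alpha = bonferroni_alpha(len(u))
    edits: list[tuple[float, int, str, str]] = []
    for j, cj in enumerate(u):
        d = int(nbase[j].sum() + delc[j])
        if d < 2:
            continue
        aligned_max = int(nbase[j].max())
        for a_idx, a in enumerate(BASES):
            if a == cj:
                continue
            K = int(nbase[j, a_idx])
            if K and K == aligned_max and K > int(nbase[j, encode_kmer(cj)]):
                p = column_tail(K, d, eps)
                if p <= alpha:
                    edits.append((p, j, "sub", a))
        K = int(delc[j])
        if K > int(nbase[j].sum()):
            p = column_tail(K, d, eps)
            if p <= alpha:
                edits.append((p, j, "del", ""))
        for a_idx, a in enumerate(BASES):
            # several insertions can pile up between the same two columns,
            # so cap the count at the column depth
            K = min(int(insc[j, a_idx]), d)
            if 2 * K > d:
                p = column_tail(K, d, eps)
                if p <= alpha:
                    edits.append((p, j, "ins", a))
    return edits


def ma_polish(
    u: str,
    region: str,
    *,
    passes: int = PASS_BUDGET,
) -> str:
    """Polish ``u`` against ``region`` via multiple-alignment column tests.

    Each pass realigns the region to the current unit, estimates the
    average per-base error rate eps from the alignment, applies at most
    one (the most significant) edit per unit position, and stops at a
    fixpoint.  Units whose alignment depth is below 2 are returned
    unchanged: a single copy carries no column evidence.
    """
    for _ in range(passes):
        if not u:
            return u
        res = wraparound_align(u, region, with_columns=True)
        if res.copies < 2.0:
            return u
        nbase, delc, insc = res.column_counts
        eps = res.delta / res.columns if res.columns else 0.0
        edits = _column_edits(u, nbase, delc, insc, eps)
        if not edits:
            return u
        chosen: dict[int, tuple[float, str, str]] = {}
        for p, j, op, a in edits:
            if j not in chosen or p < chosen[j][0]:
                chosen[j] = (p, op, a)
        out = []
        for j, cj in enumerate(u):
            _, op, a = chosen.get(j, (None, "keep", ""))
            if op == "sub":
                out.append(a)
            elif op == "del":
                pass
            elif op == "ins":
                out.append(cj)
                out.append(a)
            else:
                out.append(cj)
        new_u = "".join(out)
        if new_u == u:
            return u
        u = new_u
    return u
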