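"""Numba kernels for the two inner loops.

``window_similarity_scan`` maintains the two sliding k-mer count vectors and
their comparison statistics incrementally, so a full scan of a read at one
(k, w) pattern is O(|R|) regardless of k.

``wraparound_dp`` aligns a region against an unbounded tandem concatenation
of a unit with unit edit costs.  DP columns are the unit phases 0..L; a free
epsilon-transition identifies phase L with phase 0 (the wrap), handled with a
second left-to-right pass per row.  Row 0 is all-zero, so the alignment may
start at any phase of the unit (the unit is defined only up to rotation).
Pointers are kept for traceback.
"""

import numpy as np
from numba import njit

# pointer codes for wraparound_dp
_P_START = 0
_P_DIAG = 1
_P_VERT = 2  # region char consumed, unit phase unchanged (insertion into unit)
_P_HORIZ = 3  # unit char consumed, no region char (deletion from region)
_P_WRAP = 4


@njit(cache=True)
def window_similarity_scan(codes, n, w, k, nbins, pearson):  # pragma: no cover
    """S[i] = similarity of windows R[i, i+w] and R[i+w, i+2w], i = 0..n-2w.

    ``codes`` holds the k-mer code at every start position of the read.
    Returns an empty array when n < 2w.
    """
    m = n - 2 * w + 1
    if m <= 0:
        return np.empty(0, np.float64)
    S = np.empty(m, np.float64)
    c1 = np.zeros(nbins, np.int64)
    c2 = np.zeros(nbins, np.int64)
    nk = w - k + 1  # k-mers per window
    for p in range(nk):
        c1[codes[p]] += 1
        c2[codes[p + w]] += 1
    l1 = np.int64(0)
    dot = np.int64(0)
    q1 = np.int64(0)
    q2 = np.int64(0)
    for x in range(nbins):
        d = c1[x] - c2[x]
        l1 += d if d >= 0 else -d
        dot += c1[x] * c2[x]
        q1 += c1[x] * c1[x]
        q2 += c2[x] * c2[x]
    mu = nk / nbins
    nmu2 = nbins * mu * mu
    for i in range(m):
        if pearson:
            v1 = q1 - nmu2
            v2 = q2 - nmu2
            if v1 <= 1e-12 or v2 <= 1e-12:
                S[i] = 0.5
            else:
                rho = (dot - nmu2) / np.sqrt(v1 * v2)
                S[i] = (rho + 1.0) / 2.0
        else:
            S[i] = 1.0 - l1 / (2.0 * w)
        if i == m - 1:
            break
        # slide both windows one base to the right: four single-bin updates
        for upd in range(4):
            if upd == 0:
                x = codes[i]
                which = 0
                d = -1
            elif upd == 1:
                x = codes[i + nk]
                which = 0
                d = 1
            elif upd == 2:
                x = codes[i + w]
                which = 1
                d = -1
            else:
                x = codes[i + w + nk]
                which = 1
                d = 1
            if which == 0:
                old = c1[x]
                diff = old - c2[x]
                l1 -= diff if diff >= 0 else -diff
                diff2 = old + d - c2[x]
                l1 += diff2 if diff2 >= 0 else -diff2
                dot += d * c2[x]
                q1 += 2 * d * old + 1
                c1[x] = old + d
            else:
                old = c2[x]
                diff = c1[x] - old
                l1 -= diff if diff >= 0 else -diff
                diff2 = c1[x] - (old + d)
                l1 += diff2 if diff2 >= 0 else -diff2
                dot += d * c1[x]
                q2 += 2 * d * old + 1
                c2[x] = old + d
    return S


@njit(cache=True)
def wraparound_dp(region, unit):  # pragma: no cover
    """Wraparound edit-distance DP of a digit region against a cyclic unit.

    Returns (delta, end_j, ptr, rowmin) where rowmin[i] is the minimum edit
    cost of any wraparound alignment of the length-i prefix of the region.
    """
    m = region.shape[0]
    L = unit.shape[0]
    prev = np.zeros(L + 1, np.int64)  # row 0: free starting phase
    cur = np.empty(L + 1, np.int64)
    ptr = np.zeros((m + 1, L + 1), np.uint8)
    rowmin = np.empty(m + 1, np.int64)
    rowmin[0] = 0
    for i in range(1, m + 1):
        r = region[i - 1]
        cur[0] = prev[0] + 1
        ptr[i, 0] = _P_VERT
        for j in range(1, L + 1):
            cost = 0 if r == unit[j - 1] else 1
            best = prev[j - 1] + cost
            op = _P_DIAG
            if prev[j] + 1 < best:
                best = prev[j] + 1
                op = _P_VERT
            if cur[j - 1] + 1 < best:
                best = cur[j - 1] + 1
                op = _P_HORIZ
            cur[j] = best
            ptr[i, j] = op
        # wrap pass: phase L == phase 0, then re-propagate deletions
        if cur[L] < cur[0]:
            cur[0] = cur[L]
            ptr[i, 0] = _P_WRAP
        for j in range(1, L + 1):
            if cur[j - 1] + 1 < cur[j]:
                cur[j] = cur[j - 1] + 1
                ptr[i, j] = _P_HORIZ
        mn = cur[0]
        for j in range(1, L + 1):
            if cur[j] < mn:
                mn = cur[j]
        rowmin[i] = mn
        prev, cur = cur, prev
    end_j = 0
    delta = prev[0]
    for j in range(1, L + 1):
        if prev[j] < delta:
            delta = prev[j]
            end_j = j
    return delta, end_j, ptr, rowmin


@njit(cache=True)
def wraparound_traceback(ptr, end_j, region, unit):  # pragma: no cover
    """Walk the pointer matrix back from (m, end_j).

    Returns (consumed, matches, columns, match_flags, nbase, delc, insc):
    consumed = unit characters traversed (copies = consumed / L);
    match_flags[i] = 1 when region base i sits in a matching column;
    nbase[j, a] / delc[j] / insc[j, a] are the multiple-alignment column
    counts at unit position j+1 (aligned base a, deletion of the unit char,
    base a inserted after the position).
    """
    m = region.shape[0]
    L = unit.shape[0]
    nbase = np.zeros((L, 4), np.int64)
    delc = np.zeros(L, np.int64)
    insc = np.zeros((L, 4), np.int64)
    match_flags = np.zeros(m, np.uint8)
    i = m
    j = end_j
    consumed = np.int64(0)
    matches = np.int64(0)
    columns = np.int64(0)
    while i > 0:
        op = ptr[i, j]
        if op == _P_DIAG:
            b = region[i - 1]
            nbase[j - 1, b] += 1
            if b == unit[j - 1]:
                matches += 1
                match_flags[i - 1] = 1
            consumed += 1
            columns += 1
            i -= 1
            j -= 1
        elif op == _P_VERT:
            jj = j - 1 if j > 0 else L - 1  # insertion after phase 0 == after L
            insc[jj, region[i - 1]] += 1
            columns += 1
            i -= 1
        elif op == _P_HORIZ:
            delc[j - 1] += 1
            consumed += 1
            columns += 1
            j -= 1
        elif op == _P_WRAP:
            j = L
        else:
            break
    return consumed, matches, columns, match_flags, nbase, delc, insc
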