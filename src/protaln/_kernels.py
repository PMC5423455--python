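"""Numba inner loops: FM-index rank/search and banded affine-gap DP.

These kernels operate on the raw arrays held by :class:`protaln.index.FMIndex`
so the per-read hot path (matching statistics, suffix-array walks,
Smith-Waterman extension) runs at native speed.  All functions are pure and
deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -(10**8)


@njit(cache=True)
def occ(bwt, occ_ck, stride, c, i):
    """Number of occurrences of symbol ``c`` in ``bwt[:i]``."""
    if c >= occ_ck.shape[1]:
        return 0
    block = i // stride
    n = occ_ck[block, c]
    for k in range(block * stride, i):
        if bwt[k] == c:
            n += 1
    return n


@njit(cache=True)
def lf(row, bwt, occ_ck, stride, counts_before, sent_rows, sent_ids):
    c = bwt[row]
    if c == 0:
        idx = np.searchsorted(sent_rows, row)
        return sent_ids[idx]
    return counts_before[c] + occ(bwt, occ_ck, stride, c, row)


@njit(cache=True)
def backward_search(pattern, bwt, occ_ck, stride, counts_before, n_total):
    """Interval [l, r) of rows whose suffixes start with ``pattern``."""
    l = 0
    r = n_total
    for i in range(len(pattern) - 1, -1, -1):
        c = pattern[i]
        if c <= 0 or c >= counts_before.shape[0] - 1:
            return 0, 0
        l = counts_before[c] + occ(bwt, occ_ck, stride, c, l)
        r = counts_before[c] + occ(bwt, occ_ck, stride, c, r)
        if l >= r:
            return 0, 0
    return l, r


@njit(cache=True)
def matching_statistics(q, bwt, occ_ck, stride, counts_before, n_total):
    """starts[j] = smallest s such that q[s:j] occurs in the text.

    starts[j] == j means even the single symbol q[j-1] is absent.
    """
    n = len(q)
    starts = np.empty(n + 1, dtype=np.int64)
    starts[0] = 0
    for j in range(1, n + 1):
        l = 0
        r = n_total
        i = j - 1
        while i >= 0:
            c = q[i]
            if c <= 0 or c >= counts_before.shape[0] - 1:
                break
            l2 = counts_before[c] + occ(bwt, occ_ck, stride, c, l)
            r2 = counts_before[c] + occ(bwt, occ_ck, stride, c, r)
            if l2 >= r2:
                break
            l = l2
            r = r2
            i -= 1
        starts[j] = i + 1
    return starts


@njit(cache=True)
def sa_lookup(row, bwt, occ_ck, stride, counts_before, sent_rows, sent_ids,
              sampled, sample_rank, samples):
    steps = 0
    while sampled[row] == 0:
        row = lf(row, bwt, occ_ck, stride, counts_before, sent_rows, sent_ids)
        steps += 1
    return samples[sample_rank[row]] + steps


@njit(cache=True)
def banded_sw(q, r, score_mat, gap_open, gap_extend, d0, band):
    """Banded local alignment with affine gaps (gap of length k costs
    open + k*extend).  Cells are restricted to |(j - i) - d0| <= band.

    Returns (score, q_begin, q_end, r_begin, r_end, ops, lens, n_ops) where
    ops are 0=M (consumes both), 1=I (query only), 2=D (ref only), describing
    the alignment of q[q_begin:q_end] to r[r_begin:r_end].
    """
    m = len(q)
    n = len(r)
    H = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)
    # 0=stop, 1=diag, 2=from E (I), 3=from F (D)
    tbH = np.zeros((m + 1, n + 1), dtype=np.uint8)
    tbE = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 1=open, 0=extend
    tbF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    for i in range(m + 1):
        jlo = i + d0 - band
        jhi = i + d0 + band
        if jlo < 0:
            jlo = 0
        if jhi > n:
            jhi = n
        for j in range(jlo, jhi + 1):
            H[i, j] = 0
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        jlo = i + d0 - band
        jhi = i + d0 + band
        if jlo < 1:
            jlo = 1
        if jhi > n:
            jhi = n
        for j in range(jlo, jhi + 1):
            # E: gap consuming query (I) -- from row above, same column
            e_open = H[i - 1, j] - gap_open - gap_extend
            e_ext = E[i - 1, j] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                tbE[i, j] = 1
            else:
                E[i, j] = e_ext
            # F: gap consuming reference (D)
            f_open = H[i, j - 1] - gap_open - gap_extend
            f_ext = F[i, j - 1] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                tbF[i, j] = 1
            else:
                F[i, j] = f_ext
            diag = H[i - 1, j - 1] + score_mat[q[i - 1], r[j - 1]]
            h = 0
            t = 0
            if diag > h:
                h = diag
                t = 1
            if E[i, j] > h:
                h = E[i, j]
                t = 2
            if F[i, j] > h:
                h = F[i, j]
                t = 3
            H[i, j] = h
            tbH[i, j] = t
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    ops = np.empty(m + n + 2, dtype=np.int8)
    lens = np.empty(m + n + 2, dtype=np.int32)
    n_ops = 0
    i = bi
    j = bj
    state = 0  # 0 in H, 1 in E, 2 in F
    while True:
        if state == 0:
            t = tbH[i, j]
            if t == 0:
                break
            if t == 1:
                op = 0
                i -= 1
                j -= 1
            elif t == 2:
                state = 1
                continue
            else:
                state = 2
                continue
        elif state == 1:
            op = 1
            if tbE[i, j] == 1:
                state = 0
            i -= 1
        else:
            op = 2
            if tbF[i, j] == 1:
                state = 0
            j -= 1
        if n_ops > 0 and ops[n_ops - 1] == op:
            lens[n_ops - 1] += 1
        else:
            ops[n_ops] = op
            lens[n_ops] = 1
            n_ops += 1
    # ops were collected end-to-start; reverse
    ops[:n_ops] = ops[:n_ops][::-1].copy()
    lens[:n_ops] = lens[:n_ops][::-1].copy()
    return best, i, bi, j, bj, ops, lens, n_ops
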