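"""Affine-gap local (Smith–Waterman) and global (Needleman–Wunsch) alignment.

These numba kernels are the in-repo HSP engine used by every search stage:
translated screening (BLOSUM62, gap 11/1), nucleotide taxonomy assignment
(+2/−3, gap 5/2) and the clustering distance (global BLOSUM62).  Gap costs
follow the BLAST convention: a gap of length k costs ``open + k*extend``.

Identity is computed over aligned columns; gap columns count as non-matches
and symbols flagged non-countable (X, stop, N) never count as identities.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**8)

# result vector layout shared by the kernels
R_SCORE, R_Q0, R_Q1, R_S0, R_S1, R_MATCH, R_COLS = range(7)


@njit(cache=True)
def sw_align(a, b, S, gap_open, gap_extend, countable):  # pragma: no cover
    """Optimal local alignment of encoded sequences a (query) and b (subject).

    Returns int64[7]: score, a_start, a_end, b_start, b_end, matches, columns
    (spans 0-based half-open; all zeros when no positive-scoring pair exists).
    """
    n = a.shape[0]
    m = b.shape[0]
    go = gap_open + gap_extend
    ge = gap_extend
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 E, 3 F
    ptrE = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 opened, 1 extended
    ptrF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - go
            e_ext = E[i, j - 1] - ge
            if e_ext > e_open:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] - go
            f_ext = F[i - 1, j] - ge
            if f_ext > f_open:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            else:
                F[i, j] = f_open
            diag = H[i - 1, j - 1] + S[ai, b[j - 1]]
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    out = np.zeros(7, dtype=np.int64)
    if best <= 0:
        return out
    # traceback
    i = bi
    j = bj
    matches = 0
    cols = 0
    state = 0  # 0=H, 2=E, 3=F
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                cols += 1
                if a[i - 1] == b[j - 1] and countable[a[i - 1]]:
                    matches += 1
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 2:
            cols += 1
            if ptrE[i, j] == 0:
                state = 0
            j -= 1
        else:
            cols += 1
            if ptrF[i, j] == 0:
                state = 0
            i -= 1
    out[R_SCORE] = best
    out[R_Q0] = i
    out[R_Q1] = bi
    out[R_S0] = j
    out[R_S1] = bj
    out[R_MATCH] = matches
    out[R_COLS] = cols
    return out


@njit(cache=True)
def nw_align(a, b, S, gap_open, gap_extend, countable):  # pragma: no cover
    """Optimal global alignment; returns int64[3]: score, matches, columns."""
    n = a.shape[0]
    m = b.shape[0]
    go = gap_open + gap_extend
    ge = gap_extend
    H = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    H[0, 0] = 0
    for j in range(1, m + 1):
        E[0, j] = -(gap_open + j * ge)
        H[0, j] = E[0, j]
        ptrH[0, j] = 2
        if j > 1:
            ptrE[0, j] = 1
    for i in range(1, n + 1):
        F[i, 0] = -(gap_open + i * ge)
        H[i, 0] = F[i, 0]
        ptrH[i, 0] = 3
        if i > 1:
            ptrF[i, 0] = 1
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - go
            e_ext = E[i, j - 1] - ge
            if e_ext > e_open:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] - go
            f_ext = F[i - 1, j] - ge
            if f_ext > f_open:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            else:
                F[i, j] = f_open
            diag = H[i - 1, j - 1] + S[ai, b[j - 1]]
            h = diag
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
    i = n
    j = m
    matches = 0
    cols = 0
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            p = ptrH[i, j]
            if p == 1:
                cols += 1
                if a[i - 1] == b[j - 1] and countable[a[i - 1]]:
                    matches += 1
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 2:
            cols += 1
            if ptrE[i, j] == 0:
                state = 0
            j -= 1
        else:
            cols += 1
            if ptrF[i, j] == 0:
                state = 0
            i -= 1
    out = np.zeros(3, dtype=np.int64)
    out[0] = H[n, m]
    out[1] = matches
    out[2] = cols
    return out


@njit(cache=True)
def sw_align_pairs(
    qbuf, qoff, qlen, sbuf, soff, slen, pair_q, pair_s, S, gap_open, gap_extend, countable
):  # pragma: no cover
    """Batch local alignment of (query, subject) index pairs.

    Sequences live concatenated in ``qbuf``/``sbuf`` with offset/length
    arrays.  Returns an (n_pairs, 7) int64 array in the sw_align layout.
    """
    n_pairs = pair_q.shape[0]
    out = np.zeros((n_pairs, 7), dtype=np.int64)
    for k in range(n_pairs):
        qi = pair_q[k]
        si = pair_s[k]
        a = qbuf[qoff[qi] : qoff[qi] + qlen[qi]]
        b = sbuf[soff[si] : soff[si] + slen[si]]
        out[k] = sw_align(a, b, S, gap_open, gap_extend, countable)
    return out


def identity_of(res: np.ndarray) -> float:
    """Identity = countable matches / aligned columns for a kernel result."""
    cols = int(res[R_COLS])
    return float(res[R_MATCH]) / cols if cols else 0.0
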