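"""Slow, exhaustive dynamic-programming reference aligner.

A deliberately naive pure-Python implementation kept fully independent of the
numba kernels in ``_align``; used only for verification on short sequences.
It enumerates the three-state affine DP (match / gap-in-a / gap-in-b) with
explicit recurrences and no shared code with the production engine.
"""

from __future__ import annotations

NEG = float("-inf")


def local_score(a, b, S, gap_open: int, gap_extend: int) -> int:
    """Best Smith–Waterman score (affine: gap of length k costs open+k*ext)."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + S[a[i - 1], b[j - 1]],
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return int(best)


def global_score(a, b, S, gap_open: int, gap_extend: int) -> int:
    """Best Needleman–Wunsch score under the same affine convention."""
    n, m = len(a), len(b)
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = -(gap_open + j * gap_extend)
        H[0][j] = E[0][j]
    for i in range(1, n + 1):
        F[i][0] = -(gap_open + i * gap_extend)
        H[i][0] = F[i][0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            H[i][j] = max(H[i - 1][j - 1] + S[a[i - 1], b[j - 1]], E[i][j], F[i][j])
    return int(H[n][m])
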