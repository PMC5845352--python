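"""Numba-compiled dynamic-programming kernels.

These are plain O(m*n) edit-distance sweeps used where throughput matters:
the gold-standard builder's genome scans and the per-match traceback fills.
They are deliberately textbook DP (no bit-parallelism) so they stay an
independent cross-check of the Myers bit-vector path in :mod:`fem.verify`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def semiglobal_end_row(pattern: np.ndarray, text: np.ndarray) -> np.ndarray:
    """ed_end[j] = min over s of edit distance(pattern, text[s..j]).

    Semi-global: the pattern is consumed fully, text start is free.  Output
    index j is the 0-based text position of the alignment's last character.
    """
    m, n = len(pattern), len(text)
    col = np.empty(m + 1, np.int32)
    for i in range(m + 1):
        col[i] = i
    out = np.empty(n, np.int32)
    for j in range(n):
        diag = col[0]
        col[0] = 0
        for i in range(1, m + 1):
            sub = diag + (0 if pattern[i - 1] == text[j] else 1)
            diag = col[i]
            best = sub
            if col[i] + 1 < best:
                best = col[i] + 1
            if col[i - 1] + 1 < best:
                best = col[i - 1] + 1
            col[i] = best
        out[j] = col[m]
    return out


@njit(cache=False)
def global_last_row(pattern: np.ndarray, text: np.ndarray) -> np.ndarray:
    """row[u] = global edit distance(pattern, text[:u]) for u = 0..len(text)."""
    m, n = len(pattern), len(text)
    col = np.empty(m + 1, np.int32)
    for i in range(m + 1):
        col[i] = i
    out = np.empty(n + 1, np.int32)
    out[0] = m
    for j in range(n):
        diag = col[0]
        col[0] = j + 1
        for i in range(1, m + 1):
            sub = diag + (0 if pattern[i - 1] == text[j] else 1)
            diag = col[i]
            best = sub
            if col[i] + 1 < best:
                best = col[i] + 1
            if col[i - 1] + 1 < best:
                best = col[i - 1] + 1
            col[i] = best
        out[j + 1] = col[m]
    return out


@njit(cache=False)
def global_matrix(pattern: np.ndarray, text: np.ndarray) -> np.ndarray:
    """Full global DP matrix (m+1) x (n+1), for traceback."""
    m, n = len(pattern), len(text)
    D = np.empty((m + 1, n + 1), np.int32)
    for i in range(m + 1):
        D[i, 0] = i
    for j in range(1, n + 1):
        D[0, j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sub = D[i - 1, j - 1] + (0 if pattern[i - 1] == text[j - 1] else 1)
            best = sub
            if D[i - 1, j] + 1 < best:
                best = D[i - 1, j] + 1
            if D[i, j - 1] + 1 < best:
                best = D[i, j - 1] + 1
            D[i, j] = best
    return D


@njit(cache=False)
def hamming_scan(read: np.ndarray, text: np.ndarray, e: int) -> np.ndarray:
    """All start positions where read matches text with <= e mismatches."""
    m, n = len(read), len(text)
    buf = np.empty(n, np.int64)
    cnt = 0
    for s in range(n - m + 1):
        d = 0
        for t in range(m):
            if read[t] != text[s + t]:
                d += 1
                if d > e:
                    break
        if d <= e:
            buf[cnt] = s
            cnt += 1
    return buf[:cnt].copy()
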