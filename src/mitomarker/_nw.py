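"""Numba kernels for affine-gap Needleman-Wunsch dynamic programming.

Two kernels share the same recurrence and traceback conventions: one over
raw character codes (pairwise sequence alignment; identical characters
match, anything else mismatches, so ambiguity codes match only themselves)
and one over column-frequency profiles (profile-profile alignment for
progressive MSA).  Gap cost for a gap of length k is
``gap_open + (k - 1) * gap_extend`` (both negative); tie-breaking in the
traceback is fixed (diagonal > up > left) so outputs are bit-reproducible.

An optional band restricts cells to ``|j - i - shift|`` within the band
half-width around the main diagonal (shifted for unequal lengths); callers
guarantee the band is wide enough to contain an optimal path or pass 0 for
the full matrix.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30

# traceback op codes
DIAG, UP, LEFT = 0, 1, 2


@njit(cache=True)
def _band_limits(i, n, m, band):
    if band <= 0:
        return 0, m
    dmin = min(0, m - n) - band
    dmax = max(0, m - n) + band
    lo = max(0, i + dmin)
    hi = min(m, i + dmax)
    return lo, hi


@njit(cache=True)
def nw_chars(a, b, match, mismatch, gap_open, gap_extend, band):
    """Affine NW over uint8 codes; returns (score, ops int8 array).

    ops is the traceback path from (0,0) to (n,m): 0 diagonal, 1 up
    (consume a), 2 left (consume b).
    """
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)   # gap in b: consumes a, moves up
    Iy = np.full((n + 1, m + 1), NEG)   # gap in a: consumes b, moves left
    # predecessor state (0=M,1=Ix,2=Iy) for each matrix
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + (i - 1) * gap_extend
        pX[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + (j - 1) * gap_extend
        pY[0, j] = 2 if j > 1 else 0
    for i in range(1, n + 1):
        lo, hi = _band_limits(i, n, m, band)
        for j in range(max(1, lo), hi + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            # M: best predecessor at (i-1, j-1), diagonal step
            best = M[i - 1, j - 1]
            arg = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                arg = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                arg = 2
            if best > NEG / 2:
                M[i, j] = best + s
                pM[i, j] = arg
            # Ix: gap in b (vertical)
            o = M[i - 1, j] + gap_open
            e = Ix[i - 1, j] + gap_extend
            if o >= e:
                Ix[i, j] = o
                pX[i, j] = 0
            else:
                Ix[i, j] = e
                pX[i, j] = 1
            # Iy: gap in a (horizontal)
            o = M[i, j - 1] + gap_open
            e = Iy[i, j - 1] + gap_extend
            if o >= e:
                Iy[i, j] = o
                pY[i, j] = 0
            else:
                Iy[i, j] = e
                pY[i, j] = 2
    # final state choice: diagonal (M) preferred, then up (Ix), then left (Iy)
    state = 0
    score = M[n, m]
    if Ix[n, m] > score:
        score = Ix[n, m]
        state = 1
    if Iy[n, m] > score:
        score = Iy[n, m]
        state = 2
    ops = np.empty(n + m, dtype=np.int8)
    k = ops.shape[0]
    i, j = n, m
    while i > 0 or j > 0:
        k -= 1
        if state == 0:
            prev = pM[i, j]
            ops[k] = DIAG
            i -= 1
            j -= 1
        elif state == 1:
            prev = pX[i, j]
            ops[k] = UP
            i -= 1
        else:
            prev = pY[i, j]
            ops[k] = LEFT
            j -= 1
        state = prev
    return score, ops[k:]


@njit(cache=True)
def nw_profiles(fa, fb, match, mismatch, gap_open, gap_extend, band):
    """Affine NW over column-frequency profiles (ncols x nsymbols).

    Column pair score: sum over symbol pairs of freq products, match for
    identical symbols, mismatch otherwise; gap mass contributes zero.
    """
    n, m = fa.shape[0], fb.shape[0]
    k = fa.shape[1]
    sa = np.empty(n)
    sb = np.empty(m)
    for i in range(n):
        sa[i] = fa[i].sum()
    for j in range(m):
        sb[j] = fb[j].sum()
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + (i - 1) * gap_extend
        pX[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + (j - 1) * gap_extend
        pY[0, j] = 2 if j > 1 else 0
    for i in range(1, n + 1):
        lo, hi = _band_limits(i, n, m, band)
        for j in range(max(1, lo), hi + 1):
            dot = 0.0
            for c in range(k):
                dot += fa[i - 1, c] * fb[j - 1, c]
            s = match * dot + mismatch * (sa[i - 1] * sb[j - 1] - dot)
            best = M[i - 1, j - 1]
            arg = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                arg = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                arg = 2
            if best > NEG / 2:
                M[i, j] = best + s
                pM[i, j] = arg
            o = M[i - 1, j] + gap_open
            e = Ix[i - 1, j] + gap_extend
            if o >= e:
                Ix[i, j] = o
                pX[i, j] = 0
            else:
                Ix[i, j] = e
                pX[i, j] = 1
            o = M[i, j - 1] + gap_open
            e = Iy[i, j - 1] + gap_extend
            if o >= e:
                Iy[i, j] = o
                pY[i, j] = 0
            else:
                Iy[i, j] = e
                pY[i, j] = 2
    state = 0
    score = M[n, m]
    if Ix[n, m] > score:
        score = Ix[n, m]
        state = 1
    if Iy[n, m] > score:
        score = Iy[n, m]
        state = 2
    ops = np.empty(n + m, dtype=np.int8)
    q = ops.shape[0]
    i, j = n, m
    while i > 0 or j > 0:
        q -= 1
        if state == 0:
            prev = pM[i, j]
            ops[q] = DIAG
            i -= 1
            j -= 1
        elif state == 1:
            prev = pX[i, j]
            ops[q] = UP
            i -= 1
        else:
            prev = pY[i, j]
            ops[q] = LEFT
            j -= 1
        state = prev
    return score, ops[q:]
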