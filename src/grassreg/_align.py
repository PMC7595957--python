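"""Numba kernel for exact affine-gap (Gotoh) global alignment.

Three-state DP: M (diagonal / substitution), X (gap in the query, i.e. the
reference base is consumed, "up"), Y (gap in the reference, "left").  A gap of
length L costs ``gap_open + (L-1)*gap_extend``.  Ties are broken with the
fixed priority diagonal > up > left, applied both when filling the pointer
matrices and when choosing the final state, so tracebacks are deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30  # effectively -inf; safe to add penalties without overflow

M_STATE, X_STATE, Y_STATE = 0, 1, 2


@njit(cache=True)
def gotoh_fill(a, b, match, mismatch, gap_open, gap_extend):
    """Fill Gotoh matrices; return (score, end_state, ptrM, ptrX, ptrY).

    ptr*[i, j] holds the predecessor state for entering state * at (i, j).
    """
    n, m = a.shape[0], b.shape[0]
    Mp = np.full(m + 1, NEG)
    Xp = np.full(m + 1, NEG)
    Yp = np.full(m + 1, NEG)
    Mc = np.empty(m + 1)
    Xc = np.empty(m + 1)
    Yc = np.empty(m + 1)
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)

    Mp[0] = 0.0
    for j in range(1, m + 1):
        Yp[j] = gap_open + (j - 1) * gap_extend
        ptrY[0, j] = Y_STATE if j > 1 else M_STATE

    for i in range(1, n + 1):
        Mc[0] = NEG
        Yc[0] = NEG
        Xc[0] = gap_open + (i - 1) * gap_extend
        ptrX[i, 0] = X_STATE if i > 1 else M_STATE
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] and ai < 4 else mismatch
            # M: predecessor at (i-1, j-1); priority M > X > Y
            best = Mp[j - 1]
            arg = M_STATE
            if Xp[j - 1] > best:
                best = Xp[j - 1]
                arg = X_STATE
            if Yp[j - 1] > best:
                best = Yp[j - 1]
                arg = Y_STATE
            Mc[j] = best + s
            ptrM[i, j] = arg
            # X (up): predecessor at (i-1, j)
            best = Mp[j] + gap_open
            arg = M_STATE
            if Xp[j] + gap_extend > best:
                best = Xp[j] + gap_extend
                arg = X_STATE
            if Yp[j] + gap_open > best:
                best = Yp[j] + gap_open
                arg = Y_STATE
            Xc[j] = best
            ptrX[i, j] = arg
            # Y (left): predecessor at (i, j-1)
            best = Mc[j - 1] + gap_open
            arg = M_STATE
            if Xc[j - 1] + gap_open > best:
                best = Xc[j - 1] + gap_open
                arg = X_STATE
            if Yc[j - 1] + gap_extend > best:
                best = Yc[j - 1] + gap_extend
                arg = Y_STATE
            Yc[j] = best
            ptrY[i, j] = arg
        Mp, Mc = Mc, Mp
        Xp, Xc = Xc, Xp
        Yp, Yc = Yc, Yp

    score = Mp[m]
    end_state = M_STATE
    if Xp[m] > score:
        score = Xp[m]
        end_state = X_STATE
    if Yp[m] > score:
        score = Yp[m]
        end_state = Y_STATE
    return score, end_state, ptrM, ptrX, ptrY


def traceback(n, m, end_state, ptrM, ptrX, ptrY):
    """Recover the alignment path as a list of (move) with move in {M,X,Y}."""
    moves = []
    i, j, state = n, m, end_state
    while i > 0 or j > 0:
        moves.append(state)
        if state == M_STATE:
            state = ptrM[i, j]
            i, j = i - 1, j - 1
        elif state == X_STATE:
            state = ptrX[i, j]
            i -= 1
        else:
            state = ptrY[i, j]
            j -= 1
    moves.reverse()
    return moves
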