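"""Numba kernel for global profile-profile alignment with affine gaps
(Gotoh three-state dynamic programme with packed traceback)."""

from __future__ import annotations

import numpy as np
from numba import njit

# operation codes emitted by the traceback
OP_MATCH = 0  # consume one column of each profile
OP_CONSUME_A = 1  # column of A against a new gap in B
OP_CONSUME_B = 2  # column of B against a new gap in A

_NEG = -1.0e30

# DP states; tie preference is MATCH, then gap-in-first (consume B), then
# gap-in-second (consume A)
_S_M, _S_GB, _S_GA = 0, 1, 2


@njit(cache=True)
def gotoh_align(score: np.ndarray, gap_open: float, gap_extend: float):
    """Align two profiles given their column-pair score matrix.

    Returns (ops, n_ops, best_score); ops is in forward order using the
    OP_* codes above.  Terminal gaps pay the same affine penalties as
    internal ones.
    """
    n1, n2 = score.shape
    m_prev = np.full(n2 + 1, _NEG)
    ga_prev = np.full(n2 + 1, _NEG)
    gb_prev = np.full(n2 + 1, _NEG)
    m_cur = np.full(n2 + 1, _NEG)
    ga_cur = np.full(n2 + 1, _NEG)
    gb_cur = np.full(n2 + 1, _NEG)
    # packed 2-bit predecessor states: bits 0-1 for M, 2-3 for GB, 4-5 for GA
    ptr = np.zeros((n1 + 1, n2 + 1), dtype=np.uint8)

    m_prev[0] = 0.0
    for j in range(1, n2 + 1):
        gb_prev[j] = -gap_open - (j - 1) * gap_extend
        ptr[0, j] |= np.uint8(_S_GB << 2)

    for i in range(1, n1 + 1):
        m_cur[0] = _NEG
        gb_cur[0] = _NEG
        if i == 1:
            ga_cur[0] = -gap_open
            ptr[i, 0] |= np.uint8(_S_M << 4)
        else:
            ga_cur[0] = ga_prev[0] - gap_extend
            ptr[i, 0] |= np.uint8(_S_GA << 4)
        for j in range(1, n2 + 1):
            # M: diagonal move from any state at (i-1, j-1)
            best = m_prev[j - 1]
            state = _S_M
            if gb_prev[j - 1] > best:
                best = gb_prev[j - 1]
                state = _S_GB
            if ga_prev[j - 1] > best:
                best = ga_prev[j - 1]
                state = _S_GA
            m_cur[j] = best + score[i - 1, j - 1]
            p = np.uint8(state)
            # GB: consume B column j (gap in A), horizontal move from (i, j-1)
            best = m_cur[j - 1] - gap_open
            state = _S_M
            if gb_cur[j - 1] - gap_extend > best:
                best = gb_cur[j - 1] - gap_extend
                state = _S_GB
            if ga_cur[j - 1] - gap_open > best:
                best = ga_cur[j - 1] - gap_open
                state = _S_GA
            gb_cur[j] = best
            p |= np.uint8(state << 2)
            # GA: consume A column i (gap in B), vertical move from (i-1, j)
            best = m_prev[j] - gap_open
            state = _S_M
            if gb_prev[j] - gap_open > best:
                best = gb_prev[j] - gap_open
                state = _S_GB
            if ga_prev[j] - gap_extend > best:
                best = ga_prev[j] - gap_extend
                state = _S_GA
            ga_cur[j] = best
            p |= np.uint8(state << 4)
            ptr[i, j] = p
        m_prev, m_cur = m_cur, m_prev
        ga_prev, ga_cur = ga_cur, ga_prev
        gb_prev, gb_cur = gb_cur, gb_prev

    # final state choice: M, then GB, then GA
    best = m_prev[n2]
    state = _S_M
    if gb_prev[n2] > best:
        best = gb_prev[n2]
        state = _S_GB
    if ga_prev[n2] > best:
        best = ga_prev[n2]
        state = _S_GA

    ops = np.empty(n1 + n2, dtype=np.int8)
    k = n1 + n2
    i, j = n1, n2
    while i > 0 or j > 0:
        p = ptr[i, j]
        if state == _S_M:
            prev = p & np.uint8(3)
            k -= 1
            ops[k] = OP_MATCH
            i -= 1
            j -= 1
        elif state == _S_GB:
            prev = (p >> 2) & np.uint8(3)
            k -= 1
            ops[k] = OP_CONSUME_B
            j -= 1
        else:
            prev = (p >> 4) & np.uint8(3)
            k -= 1
            ops[k] = OP_CONSUME_A
            i -= 1
        state = prev
    return ops[k:], best
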