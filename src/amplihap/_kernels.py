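"""Numba kernels for banded affine-gap semi-global alignment.

The band is defined around a guide diagonal: query row ``i`` may visit
reference columns ``j`` with ``|j - i - offset| <= w``.  End gaps on the
reference are free (the query must be consumed in full); the alignment is
optimal within the band.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e18

# op codes used by the kernel
OP_EQ, OP_X, OP_I, OP_D = 0, 1, 2, 3
OP_CHARS = "=XID"


@njit(cache=True)
def banded_semiglobal(q, r, match, mismatch, gap_open, gap_extend, w, offset):
    """Banded affine semi-global DP with traceback.

    Returns (ok, score, ref_start, ops, lens, n_ops).  ``ok`` is False when
    the band cannot connect the query to the reference (band overflow).
    Tie-breaks prefer diagonal moves, then insertions (I), then deletions (D).
    """
    m = q.shape[0]
    n = r.shape[0]
    W = 2 * w + 1
    H = np.full((m + 1, W), NEG)
    E = np.full((m + 1, W), NEG)  # gap in query (D: consumes ref)
    F = np.full((m + 1, W), NEG)  # gap in ref (I: consumes query)
    pH = np.zeros((m + 1, W), np.int8)  # 0 diag, 1 from F(I), 2 from E(D)
    pE = np.zeros((m + 1, W), np.int8)  # 0 open, 1 extend
    pF = np.zeros((m + 1, W), np.int8)

    for k in range(W):
        j = offset + k - w
        if 0 <= j <= n:
            H[0, k] = 0.0  # free leading reference gap
    for i in range(1, m + 1):
        ci = i + offset
        qi = q[i - 1]
        for k in range(W):
            j = ci + k - w
            if j < 0 or j > n:
                continue
            # F: insertion (consume query), from (i-1, j) -> band index k+1
            fv = NEG
            pf = 0
            if k + 1 < W:
                a = H[i - 1, k + 1] + gap_open + gap_extend
                b = F[i - 1, k + 1] + gap_extend
                if a >= b:
                    fv = a
                else:
                    fv = b
                    pf = 1
            F[i, k] = fv
            pF[i, k] = pf
            # E: deletion (consume ref), from (i, j-1) -> band index k-1
            ev = NEG
            pe = 0
            if k - 1 >= 0 and j - 1 >= 0:
                a = H[i, k - 1] + gap_open + gap_extend
                b = E[i, k - 1] + gap_extend
                if a >= b:
                    ev = a
                else:
                    ev = b
                    pe = 1
            E[i, k] = ev
            pE[i, k] = pe
            # H: best of diagonal, F, E (preference in that order on ties)
            best = NEG
            ph = 0
            if j - 1 >= 0 and H[i - 1, k] > NEG / 2:
                s = match if (qi == r[j - 1] and qi < 4) else mismatch
                best = H[i - 1, k] + s
            if fv > best:
                best = fv
                ph = 1
            if ev > best:
                best = ev
                ph = 2
            H[i, k] = best
            pH[i, k] = ph

    # free trailing reference gap: best H over the last row
    best = NEG
    bk = -1
    for k in range(W):
        j = m + offset + k - w
        if 0 <= j <= n and H[m, k] > best:
            best = H[m, k]
            bk = k
    ops = np.empty(2 * (m + n) + 4, np.int8)
    lens = np.empty(2 * (m + n) + 4, np.int64)
    if bk < 0 or best <= NEG / 2:
        return False, 0.0, 0, ops, lens, 0

    # traceback (ops emitted tail-first, reversed at the end)
    i = m
    k = bk
    j = m + offset + bk - w
    layer = 0  # 0 H, 1 F, 2 E
    n_ops = 0
    last_op = -1
    while i > 0:
        if layer == 0:
            ph = pH[i, k]
            if ph == 0:
                op = OP_EQ if (q[i - 1] == r[j - 1] and q[i - 1] < 4) else OP_X
                i -= 1
                j -= 1
            elif ph == 1:
                layer = 1
                continue
            else:
                layer = 2
                continue
        elif layer == 1:
            op = OP_I
            if pF[i, k] == 0:
                layer = 0
            i -= 1
            k += 1
        else:
            op = OP_D
            if pE[i, k] == 0:
                layer = 0
            j -= 1
            k -= 1
        if op == last_op:
            lens[n_ops - 1] += 1
        else:
            ops[n_ops] = op
            lens[n_ops] = 1
            n_ops += 1
            last_op = op
    # reverse in place
    for t in range(n_ops // 2):
        ops[t], ops[n_ops - 1 - t] = ops[n_ops - 1 - t], ops[t]
        lens[t], lens[n_ops - 1 - t] = lens[n_ops - 1 - t], lens[t]
    return True, best, j, ops, lens, n_ops
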