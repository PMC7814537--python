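"""Numba inner loops: banded alignment DP fill and pair-search frame scans.

These kernels are sequential recurrences (each cell/frame depends on its
predecessor) and dominate runtime, so they are compiled; everything else in
the package stays in plain numpy/Python.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def _lse2(a, b):
    if a == NEG_INF:
        return b
    if b == NEG_INF:
        return a
    if a < b:
        a, b = b, a
    return a + np.log1p(np.exp(b - a))


@njit(cache=True)
def banded_nw_fill(a, b, match, mismatch, gap, jlo, jhi):
    """Fill a banded global-alignment DP matrix.

    ``jlo[i]..jhi[i]`` (inclusive) is the admissible column range of DP row
    ``i``; cells outside the band stay at -inf.  Returns the score matrix and
    a traceback pointer matrix (0 unreached, 1 diagonal, 2 up/gap-in-b,
    3 left/gap-in-a); ties prefer diagonal, then up, then left.
    """
    m = a.size
    n = b.size
    M = np.full((m + 1, n + 1), NEG_INF)
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for j in range(1, jhi[0] + 1):
        M[0, j] = M[0, j - 1] + gap
        ptr[0, j] = 3
    for i in range(1, m + 1):
        for j in range(jlo[i], jhi[i] + 1):
            best = NEG_INF
            p = 0
            if j >= 1:
                s = match if a[i - 1] == b[j - 1] else mismatch
                d = M[i - 1, j - 1] + s
                if d > best:
                    best = d
                    p = 1
            u = M[i - 1, j] + gap
            if u > best:
                best = u
                p = 2
            if j >= 1:
                left = M[i, j - 1] + gap
                if left > best:
                    best = left
                    p = 3
            M[i, j] = best
            ptr[i, j] = p
    return M, ptr


@njit(cache=True)
def prefix_scan(lp_c, lp_blank, par_b, par_nb, par_lo, parent_is_empty,
                is_repeat, start, stop, own_b_prev, own_nb_prev):
    """Advance one prefix's CTC forward masses over frames [start, stop).

    ``lp_c`` / ``lp_blank`` are the log-probability columns of the prefix's
    final base and of blank.  ``par_b`` / ``par_nb`` hold the parent prefix's
    masses from frame ``par_lo`` on; frames below ``par_lo`` contribute
    nothing (that is the envelope's band truncation; with ``par_lo == 0``
    the recursion is exact).  ``own_*_prev`` are this prefix's masses at
    frame ``start - 1``.
    """
    n = stop - start
    out_b = np.empty(n)
    out_nb = np.empty(n)
    b_prev = own_b_prev
    nb_prev = own_nb_prev
    for k in range(n):
        tp = start + k - 1
        if tp == -1:
            pb = 0.0 if parent_is_empty else NEG_INF
            pnb = NEG_INF
        elif tp < par_lo or tp - par_lo >= par_b.size:
            pb = NEG_INF
            pnb = NEG_INF
        else:
            pb = par_b[tp - par_lo]
            pnb = par_nb[tp - par_lo]
        ext = pb if is_repeat else _lse2(pb, pnb)
        nb = lp_c[start + k] + _lse2(nb_prev, ext)
        b = lp_blank[start + k] + _lse2(b_prev, nb_prev)
        out_b[k] = b
        out_nb[k] = nb
        b_prev = b
        nb_prev = nb
    return out_b, out_nb


@njit(cache=True)
def blank_run_scan(lp_blank, start, stop, b_prev):
    """Forward mass of the empty prefix over frames [start, stop):
    a running sum of blank log-probabilities."""
    n = stop - start
    out = np.empty(n)
    acc = b_prev
    for k in range(n):
        acc += lp_blank[start + k]
        out[k] = acc
    return out
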