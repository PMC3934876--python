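"""Log-space dynamic-programming kernels (numba-compiled, GIL-free).

The pair-HMM forward-backward and the partition-function forward/reverse
passes are quadratic-time recursions over (l_x+1) x (l_y+1) grids.  They are
written as plain loops and compiled with numba so that thread-based worker
pools scale; all arithmetic is in log space, so sequences up to tens of
thousands of residues cannot underflow.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True, nogil=True, inline="always")
def _lae(a, b):
    """log(exp(a) + exp(b)) without overflow."""
    if a < b:
        a, b = b, a
    if b == NEG_INF:
        return a
    return a + math.log1p(math.exp(b - a))


@njit(cache=True, nogil=True)
def hmm_posterior_kernel(x, y, lpi, ltr, lem, lins):
    """Match-state posterior of the 5-state pair-HMM via forward-backward.

    States: 0 match, 1/2 short insert in x/y, 3/4 long insert in x/y.
    ``x`` and ``y`` are integer-encoded sequences; ``lpi``, ``ltr``,
    ``lem``, ``lins`` are log initial/transition/match/insert tables.
    Returns the (l_x+1) x (l_y+1) posterior grid with a zero boundary.
    """
    lx, ly = x.shape[0], y.shape[0]
    fwd = np.full((5, lx + 1, ly + 1), NEG_INF)
    for i in range(lx + 1):
        for j in range(ly + 1):
            if i == 0 and j == 0:
                continue
            if i >= 1 and j >= 1:
                acc = NEG_INF
                for s in range(5):
                    acc = _lae(acc, fwd[s, i - 1, j - 1] + ltr[s, 0])
                if i == 1 and j == 1:
                    acc = _lae(acc, lpi[0])
                fwd[0, i, j] = acc + lem[x[i - 1], y[j - 1]]
            if i >= 1:
                for s in (1, 3):  # insert-in-x states consume x_i
                    acc = _lae(fwd[0, i - 1, j] + ltr[0, s],
                               fwd[s, i - 1, j] + ltr[s, s])
                    if i == 1 and j == 0:
                        acc = _lae(acc, lpi[s])
                    fwd[s, i, j] = acc + lins[x[i - 1]]
            if j >= 1:
                for s in (2, 4):  # insert-in-y states consume y_j
                    acc = _lae(fwd[0, i, j - 1] + ltr[0, s],
                               fwd[s, i, j - 1] + ltr[s, s])
                    if i == 0 and j == 1:
                        acc = _lae(acc, lpi[s])
                    fwd[s, i, j] = acc + lins[y[j - 1]]

    total = NEG_INF
    for s in range(5):
        total = _lae(total, fwd[s, lx, ly])

    bwd = np.full((5, lx + 1, ly + 1), NEG_INF)
    for s in range(5):
        bwd[s, lx, ly] = 0.0
    for i in range(lx, -1, -1):
        for j in range(ly, -1, -1):
            if i == lx and j == ly:
                continue
            for s in range(5):
                acc = NEG_INF
                if i < lx and j < ly and ltr[s, 0] != NEG_INF:
                    acc = _lae(acc, ltr[s, 0] + lem[x[i], y[j]]
                               + bwd[0, i + 1, j + 1])
                if i < lx:
                    for t in (1, 3):
                        if ltr[s, t] != NEG_INF:
                            acc = _lae(acc, ltr[s, t] + lins[x[i]]
                                       + bwd[t, i + 1, j])
                if j < ly:
                    for t in (2, 4):
                        if ltr[s, t] != NEG_INF:
                            acc = _lae(acc, ltr[s, t] + lins[y[j]]
                                       + bwd[t, i, j + 1])
                bwd[s, i, j] = acc

    post = np.zeros((lx + 1, ly + 1))
    for i in range(1, lx + 1):
        for j in range(1, ly + 1):
            v = fwd[0, i, j] + bwd[0, i, j] - total
            if v > NEG_INF:
                p = math.exp(v)
                post[i, j] = p if p < 1.0 else 1.0
    return post


@njit(cache=True, nogil=True)
def pf_posterior_kernel(x, y, bscore, bgo, bge):
    """Match posterior of the affine-gap Boltzmann alignment ensemble.

    Every global alignment (sequence of match / gap-in-x / gap-in-y columns)
    carries weight exp(beta * (sum of substitution scores + affine gap
    penalties)); ``bscore``, ``bgo``, ``bge`` are already multiplied by beta.
    Entry (i, j) is the ensemble probability that x_i pairs with y_j:
    Z_forward(match at i,j) * Z_reverse(from match at i,j) / Z_total.
    """
    lx, ly = x.shape[0], y.shape[0]
    zm = np.full((lx + 1, ly + 1), NEG_INF)
    ze = np.full((lx + 1, ly + 1), NEG_INF)
    zf = np.full((lx + 1, ly + 1), NEG_INF)
    zm[0, 0] = 0.0
    for i in range(lx + 1):
        for j in range(ly + 1):
            if i >= 1 and j >= 1:
                prev = _lae(_lae(zm[i - 1, j - 1], ze[i - 1, j - 1]),
                            zf[i - 1, j - 1])
                zm[i, j] = bscore[x[i - 1], y[j - 1]] + prev
            if j >= 1:  # gap in x, consuming y_j
                ze[i, j] = _lae(bgo + _lae(zm[i, j - 1], zf[i, j - 1]),
                                bge + ze[i, j - 1])
            if i >= 1:  # gap in y, consuming x_i
                zf[i, j] = _lae(bgo + _lae(zm[i - 1, j], ze[i - 1, j]),
                                bge + zf[i - 1, j])
    logz = _lae(_lae(zm[lx, ly], ze[lx, ly]), zf[lx, ly])

    bm = np.full((lx + 1, ly + 1), NEG_INF)
    be = np.full((lx + 1, ly + 1), NEG_INF)
    bf = np.full((lx + 1, ly + 1), NEG_INF)
    bm[lx, ly] = 0.0
    be[lx, ly] = 0.0
    bf[lx, ly] = 0.0
    for i in range(lx, -1, -1):
        for j in range(ly, -1, -1):
            if i == lx and j == ly:
                continue
            match = NEG_INF
            if i < lx and j < ly:
                match = bscore[x[i], y[j]] + bm[i + 1, j + 1]
            acc_e = bgo + be[i, j + 1] if j < ly else NEG_INF
            acc_f = bgo + bf[i + 1, j] if i < lx else NEG_INF
            bm[i, j] = _lae(_lae(match, acc_e), acc_f)
            ext_e = bge + be[i, j + 1] if j < ly else NEG_INF
            be[i, j] = _lae(_lae(match, ext_e), acc_f)
            ext_f = bge + bf[i + 1, j] if i < lx else NEG_INF
            bf[i, j] = _lae(_lae(match, acc_e), ext_f)

    post = np.zeros((lx + 1, ly + 1))
    for i in range(1, lx + 1):
        for j in range(1, ly + 1):
            v = zm[i, j] + bm[i, j] - logz
            if v > NEG_INF:
                p = math.exp(v)
                post[i, j] = p if p < 1.0 else 1.0
    return post
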