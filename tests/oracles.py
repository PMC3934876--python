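"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities by explicit enumeration (state paths,
global alignments, monotone matchings) or by dense numpy algebra, never by
calling the dynamic-programming code paths under test.  Feasible only for
tiny problem sizes.
"""

from __future__ import annotations

import math

import numpy as np


def enumerate_hmm_posterior(cx, cy, pi, trans, match_emit, ins_emit):
    """Pair-HMM posterior by exhaustive enumeration of every state path.

    States: 0 match, 1/3 insert-in-x, 2/4 insert-in-y.  Returns the
    (l_x+1) x (l_y+1) posterior grid and the total sequence probability.
    """
    lx, ly = len(cx), len(cy)
    total = 0.0
    cell = np.zeros((lx + 1, ly + 1))

    def emit(s, i, j):
        # emission weight of entering state s with next residue(s)
        if s == 0:
            return match_emit[cx[i], cy[j]]
        if s in (1, 3):
            return ins_emit[cx[i]]
        return ins_emit[cy[j]]

    def step(i, j, s, w, matches):
        nonlocal total
        if i == lx and j == ly:
            total += w
            for m in matches:
                cell[m] += w
            return
        for t in range(5):
            p = trans[s, t]
            if p == 0.0:
                continue
            di = 1 if t in (0, 1, 3) else 0
            dj = 1 if t in (0, 2, 4) else 0
            if i + di > lx or j + dj > ly:
                continue
            w2 = w * p * emit(t, i, j)
            nm = matches + [(i + 1, j + 1)] if t == 0 else matches
            step(i + di, j + dj, t, w2, nm)

    # initial emissions: the first column of the path
    for s in range(5):
        if pi[s] == 0.0:
            continue
        di = 1 if s in (0, 1, 3) else 0
        dj = 1 if s in (0, 2, 4) else 0
        if di > lx or dj > ly:
            continue
        w = pi[s] * emit(s, 0, 0)
        matches = [(1, 1)] if s == 0 else []
        step(di, dj, s, w, matches)

    post = cell / total if total > 0 else cell
    return post, total


def enumerate_alignments(lx, ly):
    """All global alignments as column-type strings over M/E/F.

    M consumes one residue of each sequence, E is a gap in x (consumes y),
    F is a gap in y (consumes x).
    """
    out = []

    def rec(i, j, cols):
        if i == lx and j == ly:
            out.append("".join(cols))
            return
        if i < lx and j < ly:
            rec(i + 1, j + 1, cols + ["M"])
        if j < ly:
            rec(i, j + 1, cols + ["E"])
        if i < lx:
            rec(i + 1, j, cols + ["F"])

    rec(0, 0, [])
    return out


def alignment_matches(cols):
    """1-based (i, j) match cells of a column-type string."""
    i = j = 0
    matches = []
    for c in cols:
        if c == "M":
            i += 1
            j += 1
            matches.append((i, j))
        elif c == "E":
            j += 1
        else:
            i += 1
    return matches


def pf_alignment_weight(cols, cx, cy, scores, go, ge, beta):
    """Boltzmann weight of one alignment under affine gap scoring.

    Each maximal run of a single gap type pays open + (len-1) * extend; a
    run of E immediately followed by F (or vice versa) is two runs.
    """
    total = 0.0
    i = j = 0
    prev = "M"
    for c in cols:
        if c == "M":
            total += scores[cx[i], cy[j]]
            i += 1
            j += 1
        else:
            total += ge if c == prev else go
            if c == "E":
                j += 1
            else:
                i += 1
        prev = c
    return math.exp(beta * total)


def enumerate_pf_posterior(cx, cy, scores, go, ge, beta):
    """Partition-function posterior by enumerating every global alignment."""
    lx, ly = len(cx), len(cy)
    total = 0.0
    cell = np.zeros((lx + 1, ly + 1))
    for cols in enumerate_alignments(lx, ly):
        w = pf_alignment_weight(cols, cx, cy, scores, go, ge, beta)
        total += w
        for m in alignment_matches(cols):
            cell[m] += w
    return cell / total, total


def brute_force_mea(p):
    """Maximum sum of p over monotone matchings, by full enumeration."""
    lx, ly = p.shape[0] - 1, p.shape[1] - 1
    best = 0.0
    for cols in enumerate_alignments(lx, ly):
        score = sum(p[m] for m in alignment_matches(cols))
        best = max(best, score)
    return best


def dense_relax_pair(x, y, dense_table, weights, order):
    """Dense reference of the weighted consistency update for pair (x, y).

    ``dense_table[(a, b)]`` holds dense posterior grids for every ordered
    pair; ``order`` is the list of sequence indices.  Product cells absent
    from the support of P_xy are discarded (no fill-in).
    """
    p_xy = dense_table[(x, y)]
    w = weights
    num = (w[x] + w[y]) * p_xy.copy()
    denom = w[x] + w[y]
    for z in order:
        if z == x or z == y:
            continue
        num += w[z] * (dense_table[(x, z)] @ dense_table[(z, y)])
        denom += w[z]
    relaxed = num / denom
    relaxed[p_xy == 0.0] = 0.0  # no new elements
    return relaxed


def dense_consistency_round(dense_table, weights, order, tau):
    """One full consistency round on dense grids, then static filtering."""
    new = {}
    for ix, x in enumerate(order):
        for y in order[ix + 1:]:
            r = dense_relax_pair(x, y, dense_table, weights, order)
            r[r < tau] = 0.0
            new[(x, y)] = r
            new[(y, x)] = r.T.copy()
    return new


def sp_tc_reference(test_cols, ref_cols):
    """Hand SP/TC counting from explicit per-column residue maps.

    Each element of *_cols is a dict name -> residue index (1-based) for the
    non-gap cells of one column.
    """
    ref_pairs = set()
    ref_columns = []
    for col in ref_cols:
        items = sorted(col.items())
        if len(items) >= 2:
            ref_columns.append(frozenset(col.items()))
            for a in range(len(items)):
                for b in range(a + 1, len(items)):
                    ref_pairs.add((items[a], items[b]))
    test_pairs = set()
    test_columns = set()
    for col in test_cols:
        items = sorted(col.items())
        test_columns.add(frozenset(col.items()))
        for a in range(len(items)):
            for b in range(a + 1, len(items)):
                test_pairs.add((items[a], items[b]))
    sp = 100.0 * len(ref_pairs & test_pairs) / len(ref_pairs) if ref_pairs else 0.0
    reproduced = sum(
        1 for col in ref_columns
        if any(col <= tcol for tcol in test_columns)
    )
    tc = 100.0 * reproduced / len(ref_columns) if ref_columns else 0.0
    return sp, tc
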