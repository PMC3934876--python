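"""Stage IV: profile-profile MEA alignment along the guide tree, refinement.

A profile is a set of already-aligned sequences, represented as a matrix of
1-based residue indices per column (0 marks a gap).  Aligning two profiles
uses the expected-match score between their columns — the weighted average
of the relaxed pairwise posteriors over all cross-pair sequences — and the
same zero-gap-cost Needleman-Wunsch recursion as stage I, with a
deterministic traceback (diagonal preferred over up over left on ties).

Refinement repeatedly splits the alignment's rows into two random profiles
(per-row Bernoulli(1/2), resampled if a side is empty), strips all-gap
columns and realigns; the realignment is accepted unconditionally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .consistency import PosteriorTable
from .guide_tree import GuideTree, TreeNode
from .pair_posterior import mea_matrix
from .seqio import Alignment, SequenceSet


@dataclass(frozen=True)
class Profile:
    """Alignment restricted to some sequences, as residue-index columns.

    ``resmap[k, j]`` is the 1-based residue index of member ``indices[k]``
    in column j, or 0 for a gap; non-gap entries increase strictly along
    each row.
    """

    indices: tuple[int, ...]
    resmap: np.ndarray  # (len(indices), width) int

    def __post_init__(self):
        if self.resmap.ndim != 2 or self.resmap.shape[0] != len(self.indices):
            raise ValueError("resmap shape does not match member count")
        for k in range(self.resmap.shape[0]):
            row = self.resmap[k]
            nz = row[row > 0]
            if np.any(np.diff(nz) <= 0):
                raise ValueError("residue indices must increase along rows")

    @property
    def width(self) -> int:
        return self.resmap.shape[1]

    @staticmethod
    def singleton(index: int, length: int) -> "Profile":
        return Profile((index,), np.arange(1, length + 1, dtype=np.int64)[None, :])

    def drop_all_gap_columns(self) -> "Profile":
        keep = np.any(self.resmap > 0, axis=0)
        return Profile(self.indices, self.resmap[:, keep])


def profile_from_alignment(aln: Alignment, order: dict[str, int]) -> Profile:
    """Convert alignment rows to a profile using ``order`` (name -> index)."""
    indices = tuple(order[name] for name, _ in aln.rows)
    width = aln.width
    resmap = np.zeros((len(indices), width), dtype=np.int64)
    for k, (_, row) in enumerate(aln.rows):
        r = 0
        for j, ch in enumerate(row):
            if ch != "-":
                r += 1
                resmap[k, j] = r
    return Profile(indices, resmap)


def profile_to_alignment(profile: Profile, seqs: SequenceSet) -> Alignment:
    """Render a profile covering all sequences as an Alignment (input order)."""
    rows = []
    by_index = {idx: k for k, idx in enumerate(profile.indices)}
    for idx, (name, seq) in enumerate(seqs.records):
        k = by_index[idx]
        chars = [
            seq[r - 1] if r > 0 else "-" for r in profile.resmap[k]
        ]
        rows.append((name, "".join(chars)))
    return Alignment(tuple(rows), alphabet=seqs.alphabet)


def profile_posterior(a: Profile, b: Profile, table: PosteriorTable,
                      w: np.ndarray) -> np.ndarray:
    """Expected-match score grid between columns of two disjoint profiles.

    p(i, j) = sum_{x in a, y in b} w_x w_y P_xy[r_x(i), r_y(j)] / sum w_x w_y.
    Gap cells contribute zero — they index the posterior's zero boundary.
    Returned grid is (width_a + 1) x (width_b + 1) with a zero boundary.
    """
    if set(a.indices) & set(b.indices):
        raise ValueError("profiles overlap")
    p = np.zeros((a.width + 1, b.width + 1))
    denom = 0.0
    for ka, x in enumerate(a.indices):
        rx = a.resmap[ka]
        for kb, y in enumerate(b.indices):
            ry = b.resmap[kb]
            dense = np.asarray(table[(x, y)].csr.todense())
            p[1:, 1:] += float(w[x]) * float(w[y]) * dense[np.ix_(rx, ry)]
            denom += float(w[x]) * float(w[y])
    p /= denom
    return p


def align_profiles(a: Profile, b: Profile, p: np.ndarray) -> Profile:
    """Merge two profiles along the MEA path through their posterior grid.

    Ties in the traceback resolve diagonal > up (consume a) > left
    (consume b).  All-gap columns of the merge are removed.
    """
    if p.shape != (a.width + 1, b.width + 1):
        raise ValueError("posterior grid shaped for different profiles")
    m = mea_matrix(p)
    i, j = a.width, b.width
    cols: list[tuple[int, int]] = []  # (a-column or -1, b-column or -1)
    while i > 0 or j > 0:
        if i > 0 and j > 0 and m[i, j] == m[i - 1, j - 1] + p[i, j]:
            cols.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif i > 0 and m[i, j] == m[i - 1, j]:
            cols.append((i - 1, -1))
            i -= 1
        else:
            cols.append((-1, j - 1))
            j -= 1
    cols.reverse()
    na, nb = len(a.indices), len(b.indices)
    merged = np.zeros((na + nb, len(cols)), dtype=np.int64)
    for col_idx, (ca, cb) in enumerate(cols):
        if ca >= 0:
            merged[:na, col_idx] = a.resmap[:, ca]
        if cb >= 0:
            merged[na:, col_idx] = b.resmap[:, cb]
    return Profile(a.indices + b.indices, merged).drop_all_gap_columns()


def progressive_align(tree: GuideTree, table: PosteriorTable, w: np.ndarray,
                      lengths: list[int]) -> Profile:
    """Post-order traversal of the guide tree, aligning child profiles."""

    def build(node: TreeNode) -> Profile:
        if node.is_leaf:
            return Profile.singleton(node.index, lengths[node.index])
        left = build(node.left)
        right = build(node.right)
        return align_profiles(left, right,
                              profile_posterior(left, right, table, w))

    return build(tree.root)


def refine(profile: Profile, table: PosteriorTable, w: np.ndarray,
           r: int, seed: int) -> Profile:
    """Iterative refinement: r random horizontal splits and realignments.

    The split assigns each row to one side with probability 1/2 (PCG64
    generator seeded with ``seed``; resampled while a side is empty), drops
    all-gap columns from each half and realigns them; the result replaces
    the current alignment unconditionally.
    """
    if r < 0:
        raise ValueError("repetition count must be >= 0")
    n = len(profile.indices)
    if n < 2:
        return profile
    rng = np.random.Generator(np.random.PCG64(seed))
    for _ in range(r):
        while True:
            side = rng.integers(0, 2, size=n)
            if 0 < side.sum() < n:
                break
        a = Profile(
            tuple(idx for idx, s in zip(profile.indices, side) if s == 0),
            profile.resmap[side == 0],
        ).drop_all_gap_columns()
        b = Profile(
            tuple(idx for idx, s in zip(profile.indices, side) if s == 1),
            profile.resmap[side == 1],
        ).drop_all_gap_columns()
        profile = align_profiles(a, b, profile_posterior(a, b, table, w))
    return profile
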