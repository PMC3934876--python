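"""Stage II: UPGMA guide tree and ClustalW sequence weights.

The tree is classic size-weighted (arithmetic-mean) UPGMA over the stage-I
distances, which yields an ultrametric rooted binary tree: each merge sits
at half the minimum inter-cluster distance.  Ties on the minimum distance
are broken towards the lexicographically smallest pair of cluster indices so
the construction is fully deterministic.

ClustalW weighting divides each branch length evenly among the leaves below
it; a sequence's weight is the sum of its shares along the root path, which
down-weights members of tight, redundant subfamilies.  Weights are
normalised to mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

EPS_BRANCH = 1e-9  # floor for zero-length branches (duplicate sequences)


@dataclass
class TreeNode:
    """Node of the guide tree; leaves carry a sequence index."""

    height: float = 0.0
    index: Optional[int] = None           # leaf: sequence index
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.index is not None

    def leaves(self) -> list[int]:
        if self.is_leaf:
            return [self.index]
        return self.left.leaves() + self.right.leaves()

    def n_leaves(self) -> int:
        return len(self.leaves())


@dataclass(frozen=True)
class GuideTree:
    root: TreeNode
    n: int

    def leaves(self) -> list[int]:
        return self.root.leaves()

    def newick(self, names: Optional[list[str]] = None) -> str:
        """Newick string with branch lengths (parent height - child height)."""

        def fmt(node: TreeNode, parent_height: float) -> str:
            bl = max(parent_height - node.height, EPS_BRANCH)
            if node.is_leaf:
                label = names[node.index] if names else f"s{node.index}"
                return f"{label}:{bl:.6f}"
            inner = f"({fmt(node.left, node.height)},{fmt(node.right, node.height)})"
            return f"{inner}:{bl:.6f}"

        r = self.root
        if r.is_leaf:  # n == 1 degenerate, not produced by upgma
            return f"{names[r.index] if names else f's{r.index}'};"
        return (f"({fmt(r.left, r.height)},{fmt(r.right, r.height)})"
                f":0.000000;")


def check_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0.0):
        raise ValueError("distance matrix diagonal must be zero")
    if d.min() < 0.0:
        raise ValueError("distances must be non-negative")
    return d


def upgma(d: np.ndarray) -> GuideTree:
    """Size-weighted UPGMA: merge closest clusters, height = d_min / 2."""
    d = check_distance_matrix(d)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sequences for a guide tree")

    # active clusters keyed by creation order; distance updates use the
    # size-weighted average, equivalent to the mean over all member pairs
    nodes: dict[int, TreeNode] = {i: TreeNode(height=0.0, index=i) for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                key = (i, j) if i < j else (j, i)
                val = dist[key]
                if best is None or val < best[0] - 1e-15:
                    best = (val, i, j)
                # ties: keep smallest (i, j) — loop order guarantees it
        dmin, i, j = best
        merged = TreeNode(height=dmin / 2.0, left=nodes[i], right=nodes[j])
        si, sj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(next_id, k), max(next_id, k))] = (si * dik + sj * djk) / (si + sj)
        nodes[next_id] = merged
        sizes[next_id] = si + sj
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return GuideTree(root=nodes[active[0]], n=n)


def clustalw_weights(tree: GuideTree) -> np.ndarray:
    """Per-sequence weights: shared branch lengths split among leaves below.

    weight(x) = sum over root-path edges of length(edge) / leaves(edge),
    with zero-length edges floored at a tiny epsilon so duplicate sequences
    keep strictly positive weights; normalised to mean 1.
    """
    w = np.zeros(tree.n)

    def walk(node: TreeNode, parent_height: float) -> None:
        bl = parent_height - node.height
        if node.is_leaf:  # duplicates keep strictly positive weight
            bl = max(bl, EPS_BRANCH)
        share = bl / node.n_leaves()
        for leaf in node.leaves():
            w[leaf] += share
        if not node.is_leaf:
            walk(node.left, node.height)
            walk(node.right, node.height)

    root = tree.root
    walk(root.left, root.height)
    walk(root.right, root.height)
    mean = w.mean()
    if mean > 0:
        w = w / mean
    else:  # all distances zero: fall back to uniform weights
        w = np.ones(tree.n)
    return w
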