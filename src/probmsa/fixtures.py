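"""Seeded synthetic protein-family generator with recorded true alignments.

Families are simulated by evolving an ancestor sequence along a tree:
substitutions follow a Jukes-Cantor-style uniform replacement over the
20-letter alphabet, and insertions/deletions occur per site with
geometric lengths.  Homology is tracked through explicit column identities,
so the generator emits the exact reference alignment alongside the leaf
sequences, plus a full core-column mask.  Everything is deterministic under
the spec's seed.

High per-branch substitution rates push families into the twilight zone
(mean pairwise identity below 30%), the regime where consistency
information matters most.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .params import AA_ORDER
from .seqio import AMINO, Alignment, SequenceSet


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one simulated family."""

    n: int = 8                    # number of leaf sequences
    length: int = 100             # ancestor length
    sub_rate: float = 0.15        # per-site substitution probability per branch
    indel_rate: float = 0.03      # per-site indel event probability per branch
    mean_indel: float = 2.0       # mean geometric indel length
    shape: str = "random"         # balanced | star | random
    seed: int = 0

    def __post_init__(self):
        if self.n < 2 or self.length < 1:
            raise ValueError("need n >= 2 sequences and length >= 1")
        if not (0.0 <= self.sub_rate < 1.0 and 0.0 <= self.indel_rate < 1.0):
            raise ValueError("rates must lie in [0, 1)")
        if self.shape not in ("balanced", "star", "random"):
            raise ValueError(f"unknown tree shape {self.shape!r}")


def twilight_spec(seed: int, n: int = 8, length: int = 100) -> FamilySpec:
    """A family specification that lands in the twilight zone (<30% identity)."""
    return FamilySpec(n=n, length=length, sub_rate=0.5, indel_rate=0.02,
                      mean_indel=2.0, shape="star", seed=seed)


def _tree_shape(n: int, shape: str, rng: np.random.Generator):
    """Tree as nested structure; leaves are ints, internal nodes tuples.

    A 'star' is modelled as a list of leaves hanging off the root, each one
    branch from the ancestor.
    """
    if shape == "star":
        return list(range(n))
    nodes = list(range(n))
    if shape == "balanced":
        while len(nodes) > 1:
            nodes = [tuple(nodes[i:i + 2]) if len(nodes[i:i + 2]) == 2
                     else nodes[i] for i in range(0, len(nodes), 2)]
        return nodes[0]
    while len(nodes) > 1:  # random: merge uniformly chosen pairs
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = (nodes[i], nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0]


class _ColumnRegistry:
    """Global homology-column bookkeeping: insertion keeps alignment order."""

    def __init__(self, length: int):
        self.order: list[int] = list(range(length))
        self._counter = itertools.count(length)

    def insert_after(self, anchor: int | None, count: int) -> list[int]:
        new = [next(self._counter) for _ in range(count)]
        pos = 0 if anchor is None else self.order.index(anchor) + 1
        self.order[pos:pos] = new
        return new


def _mutate(seq: list[tuple[int, str]], rng: np.random.Generator,
            spec: FamilySpec, registry: _ColumnRegistry) -> list[tuple[int, str]]:
    """One branch of evolution: substitutions then indels."""
    letters = AA_ORDER
    out = []
    for col, res in seq:
        if rng.random() < spec.sub_rate:
            # uniform replacement with one of the 19 other letters
            choice = letters[rng.integers(0, 19)]
            if choice == res:
                choice = letters[19]
            res = choice
        out.append((col, res))

    p_stop = 1.0 / max(spec.mean_indel, 1.0)
    result: list[tuple[int, str]] = []
    i = 0
    while i < len(out):
        r = rng.random()
        if r < spec.indel_rate / 2.0:
            # deletion of geometric length starting at this site
            i += max(1, int(rng.geometric(p_stop)))
            continue
        if r < spec.indel_rate:
            # insertion of geometric length after this site
            k = max(1, int(rng.geometric(p_stop)))
            cols = registry.insert_after(out[i][0], k)
            result.append(out[i])
            for col in cols:
                result.append((col, letters[rng.integers(0, 20)]))
            i += 1
            continue
        result.append(out[i])
        i += 1
    return result if result else out[:1]


def _evolve(node, seq, rng, spec, registry, leaves):
    if isinstance(node, int):
        leaves[node] = seq
        return
    children = node if isinstance(node, (list, tuple)) else [node]
    for child in children:
        mutated = _mutate(seq, rng, spec, registry)
        _evolve(child, mutated, rng, spec, registry, leaves)


def evolve_family(spec: FamilySpec) -> tuple[SequenceSet, Alignment, list[int]]:
    """Simulate one family: sequences, true alignment and core-column mask.

    The core mask is full (every reference column), mirroring references
    whose alignment is known exactly from the simulated history.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    registry = _ColumnRegistry(spec.length)
    ancestor = [(j, AA_ORDER[rng.integers(0, 20)]) for j in range(spec.length)]
    shape = _tree_shape(spec.n, spec.shape, rng)
    leaves: dict[int, list[tuple[int, str]]] = {}
    if isinstance(shape, list):  # star: every leaf one branch from the root
        for leaf in shape:
            _evolve(leaf, _mutate(ancestor, rng, spec, registry),
                    rng, spec, registry, leaves)
    else:
        _evolve(shape, ancestor, rng, spec, registry, leaves)

    names = [f"seq{i}" for i in range(spec.n)]
    residues = {i: dict(leaves[i]) for i in range(spec.n)}
    used_cols = [c for c in registry.order
                 if any(c in residues[i] for i in range(spec.n))]
    rows = []
    for i in range(spec.n):
        rows.append((names[i],
                     "".join(residues[i].get(c, "-") for c in used_cols)))
    ref = Alignment(tuple(rows), alphabet=AMINO)
    seqs = ref.degapped()
    core = list(range(len(used_cols)))
    return seqs, ref, core


def identity_of(seqs: SequenceSet, ref: Alignment) -> float:
    """Mean pairwise percent identity over the reference's aligned pairs."""
    if set(seqs.names) != set(ref.names):
        raise ValueError("reference does not cover the sequence set")
    rows = dict(ref.rows)
    names = list(seqs.names)
    idents = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ra, rb = rows[names[a]], rows[names[b]]
            aligned = same = 0
            for ca, cb in zip(ra, rb):
                if ca != "-" and cb != "-":
                    aligned += 1
                    if ca == cb:
                        same += 1
            idents.append(100.0 * same / aligned if aligned else 0.0)
    return float(np.mean(idents)) if idents else 100.0
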