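"""Stage III: weighted consistency transformation over sparse posteriors.

Each pairwise posterior P_xy is relaxed through every third sequence z:

    P'_xy = [ (w_x + w_y) P_xy + sum_z w_z (P_xz P_zy) ]
            / [ (w_x + w_y) + sum_z w_z ]

so that the matrix fed to the progressive stage carries evidence from all
pairwise alignments, not just the one pair.  Two constraints shape the
sparse arithmetic: no fill-in (a product cell absent from P_xy's support is
discarded, so support can only shrink) and post-round filtering (static
threshold or, in accurate mode, per-matrix top-fraction).  A round relaxes
every pair against a snapshot of the pre-round table, so results are
independent of pair order and worker count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sparse_store import SparsePosterior, filter_adaptive, filter_static, transpose


@dataclass(frozen=True)
class FilterConfig:
    """Post-relaxation filtering: mode 'static' (tau) or 'adaptive' (fraction)."""

    mode: str = "static"
    tau: float = 0.01
    fraction: float = 0.15

    def __post_init__(self):
        if self.mode not in ("static", "adaptive"):
            raise ValueError(f"unknown filter mode {self.mode!r}")
        if not 0.0 <= self.tau < 1.0:
            raise ValueError("tau must lie in [0, 1)")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must lie in (0, 1]")

    def apply(self, s: SparsePosterior) -> SparsePosterior:
        if self.mode == "static":
            return filter_static(s, self.tau)
        return filter_adaptive(s, self.fraction)


class PosteriorTable:
    """Sparse posteriors for all ordered sequence pairs, transpose-consistent."""

    def __init__(self, n: int, matrices: dict[tuple[int, int], SparsePosterior]):
        self.n = n
        self._m = dict(matrices)

    @classmethod
    def from_upper(cls, n: int,
                   upper: dict[tuple[int, int], SparsePosterior]) -> "PosteriorTable":
        """Build the full table from upper-triangle matrices (x < y)."""
        full: dict[tuple[int, int], SparsePosterior] = {}
        for (x, y), s in upper.items():
            if not x < y:
                raise ValueError("upper table keys must satisfy x < y")
            full[(x, y)] = s
            full[(y, x)] = transpose(s)
        return cls(n, full)

    def __getitem__(self, key: tuple[int, int]) -> SparsePosterior:
        return self._m[key]

    def __contains__(self, key) -> bool:
        return key in self._m

    def pairs(self) -> list[tuple[int, int]]:
        """Canonical unordered pair order: (0,1), (0,2), ... (n-2,n-1)."""
        return [(x, y) for x in range(self.n) for y in range(x + 1, self.n)]

    def total_elements(self) -> int:
        return sum(self._m[p].nnz for p in self.pairs())

    def validate(self) -> None:
        """Check transpose-consistency across the whole table (exact)."""
        for x, y in self.pairs():
            if (x, y) not in self._m or (y, x) not in self._m:
                raise ValueError(f"missing pair ({x}, {y}) in table")
            if transpose(self._m[(x, y)]) != self._m[(y, x)]:
                raise ValueError(f"table is not transpose-consistent at ({x}, {y})")


def relax_pair(x: int, y: int, table: PosteriorTable,
               w: np.ndarray) -> SparsePosterior:
    """Weighted relaxation of P_xy through all z, entirely on sparse operands.

    Output support is a subset of P_xy's support (no fill-in); values are the
    weighted average of the direct term and the sparse products P_xz P_zy.
    """
    if x == y:
        raise ValueError("relax_pair needs two distinct sequences")
    s_xy = table[(x, y)]
    acc = (float(w[x]) + float(w[y])) * s_xy.csr
    denom = float(w[x]) + float(w[y])
    for z in range(table.n):
        if z == x or z == y:
            continue
        acc = acc + float(w[z]) * (table[(x, z)].csr @ table[(z, y)].csr)
        denom += float(w[z])
    acc = acc.tocsr() / denom
    pattern = s_xy.csr.copy()
    pattern.data = np.ones_like(pattern.data)
    masked = acc.multiply(pattern).tocsr()
    masked.sum_duplicates()
    masked.sort_indices()
    masked.eliminate_zeros()
    masked.data = np.minimum(masked.data, 1.0)
    return SparsePosterior(masked, x_id=s_xy.x_id, y_id=s_xy.y_id)


def consistency_round(table: PosteriorTable, w: np.ndarray,
                      filter_cfg: FilterConfig) -> PosteriorTable:
    """One full round: relax every pair against the pre-round snapshot.

    All relaxations read the incoming table; replacements happen only after
    every pair is done, and transposes are regenerated so the new table stays
    exactly transpose-consistent.
    """
    upper: dict[tuple[int, int], SparsePosterior] = {}
    for x, y in table.pairs():
        upper[(x, y)] = filter_cfg.apply(relax_pair(x, y, table, w))
    return PosteriorTable.from_upper(table.n, upper)


def run_consistency(table: PosteriorTable, w: np.ndarray, c: int,
                    filter_cfg: FilterConfig) -> PosteriorTable:
    """Apply ``c`` sequential consistency rounds (c = 0 returns input)."""
    if c < 0:
        raise ValueError("repetition count must be >= 0")
    for _ in range(c):
        table = consistency_round(table, w, filter_cfg)
    return table
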