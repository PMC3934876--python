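"""Dense and compressed representations of pairwise posterior matrices.

A posterior matrix for sequences x (length l_x) and y (length l_y) is an
(l_x+1) x (l_y+1) grid whose (i, j) entry, 1-based in the residues, is the
probability that residue x_i pairs with y_j in the true alignment; row 0 and
column 0 are a zero boundary.  Because most entries are negligible, matrices
are carried through the consistency stage in a compressed sparse-row form
(per-row sizes, row offsets and a flat array of (column, value) elements) —
backed here by :class:`scipy.sparse.csr_matrix`, which is exactly that layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

VALUE_TOL = 1e-9
SUM_TOL = 1e-6


@dataclass(frozen=True)
class PosteriorMatrix:
    """Dense (l_x+1) x (l_y+1) grid of aligned-pair probabilities."""

    values: np.ndarray
    x_id: str = ""
    y_id: str = ""

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("posterior grid must be at least 2x2")
        if np.any(v[0, :] != 0.0) or np.any(v[:, 0] != 0.0):
            raise ValueError("boundary row/column must be zero")
        if v.min() < 0.0 or v.max() > 1.0 + VALUE_TOL:
            raise ValueError("posterior entries must lie in [0, 1]")
        # Row/column sums of a single-model posterior are <= 1; the RMS
        # combination of two models can exceed that slightly (RMS >= mean),
        # so the type-level bound is the worst case of the combination.
        if v.sum(axis=1).max() > 2.0 + SUM_TOL or v.sum(axis=0).max() > 2.0 + SUM_TOL:
            raise ValueError("posterior row/column sums out of range")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def transpose(self) -> "PosteriorMatrix":
        return PosteriorMatrix(self.values.T.copy(), x_id=self.y_id, y_id=self.x_id)


@dataclass(frozen=True)
class SparsePosterior:
    """Compressed rows of a posterior matrix (sizes / offsets / elements)."""

    csr: sp.csr_matrix
    x_id: str = ""
    y_id: str = ""

    def __post_init__(self):
        m = self.csr
        if not sp.issparse(m) or m.format != "csr":
            raise ValueError("backing matrix must be CSR")
        m.sum_duplicates()
        if not m.has_sorted_indices:
            m.sort_indices()
        if m.nnz:
            if m.data.min() <= 0.0:
                raise ValueError("sparse values must be positive")
            if m.data.max() > 1.0 + SUM_TOL:
                raise ValueError("sparse values must not exceed 1")

    @property
    def n_rows(self) -> int:
        return self.csr.shape[0]

    @property
    def n_cols(self) -> int:
        return self.csr.shape[1]

    @property
    def nnz(self) -> int:
        return int(self.csr.nnz)

    @property
    def row_sizes(self) -> np.ndarray:
        return np.diff(self.csr.indptr)

    @property
    def row_offsets(self) -> np.ndarray:
        return self.csr.indptr[:-1].copy()

    @property
    def elements(self) -> list[tuple[int, float]]:
        """Flat row-major (column, value) pairs, sorted by column within rows."""
        return list(zip(self.csr.indices.tolist(), self.csr.data.tolist()))

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        coo = self.csr.tocoo()
        return coo.row, coo.col, coo.data

    def __eq__(self, other) -> bool:  # bit-exact structural equality
        if not isinstance(other, SparsePosterior):
            return NotImplemented
        a, b = self.csr, other.csr
        return (a.shape == b.shape
                and np.array_equal(a.indptr, b.indptr)
                and np.array_equal(a.indices, b.indices)
                and np.array_equal(a.data, b.data))


def _csr(matrix: sp.csr_matrix) -> sp.csr_matrix:
    matrix.sum_duplicates()
    matrix.sort_indices()
    matrix.eliminate_zeros()
    return matrix


def sparsify(p: PosteriorMatrix, tau: float) -> SparsePosterior:
    """Keep exactly the positive entries with value >= tau, row-major.

    The zero boundary row/column never produces elements.  ``tau`` must lie
    in [0, 1); at 0 every strictly positive entry survives.
    """
    if not 0.0 <= tau < 1.0:
        raise ValueError("tau must lie in [0, 1)")
    kept = np.where(p.values >= max(tau, np.finfo(float).tiny), p.values, 0.0)
    return SparsePosterior(_csr(sp.csr_matrix(kept)), x_id=p.x_id, y_id=p.y_id)


def densify(s: SparsePosterior) -> PosteriorMatrix:
    """Lossless inverse of :func:`sparsify` on its image."""
    return PosteriorMatrix(np.asarray(s.csr.todense(), dtype=float),
                           x_id=s.x_id, y_id=s.y_id)


def transpose(s: SparsePosterior) -> SparsePosterior:
    """Exact transpose: (i, j, v) -> (j, i, v), shape swapped."""
    return SparsePosterior(_csr(s.csr.transpose().tocsr()),
                           x_id=s.y_id, y_id=s.x_id)


def filter_static(s: SparsePosterior, tau: float) -> SparsePosterior:
    """Drop elements with value < tau, preserving order of the rest."""
    if tau <= 0.0:
        return s
    m = s.csr.copy()
    m.data = np.where(m.data >= tau, m.data, 0.0)
    return SparsePosterior(_csr(m), x_id=s.x_id, y_id=s.y_id)


def filter_adaptive(s: SparsePosterior, f: float) -> SparsePosterior:
    """Retain the ceil(f*N) largest elements of the matrix (N = element count).

    This is the per-matrix analogue of the static threshold: the cutoff is
    chosen independently for every matrix so the same fraction of evidence
    survives for distant and close sequence pairs alike.  Ties at the cutoff
    value are resolved in (row, column) lexicographic order, earliest kept,
    so the retained count is exact and deterministic.
    """
    if not 0.0 < f <= 1.0:
        raise ValueError("f must lie in (0, 1]")
    n = s.nnz
    if n == 0 or f == 1.0:
        return s
    keep = math.ceil(f * n)
    rows, cols, vals = s.coords()
    # stable sort by (-value, row, col): equal values keep earliest positions
    order = np.lexsort((cols, rows, -vals))
    sel = order[:keep]
    m = sp.csr_matrix((vals[sel], (rows[sel], cols[sel])), shape=s.csr.shape)
    return SparsePosterior(_csr(m), x_id=s.x_id, y_id=s.y_id)


def dump_tsv(s: SparsePosterior, path) -> None:
    """Debug dump as 3-column TSV (row, col, value), 1-based residue indices."""
    rows, cols, vals = s.coords()
    with open(path, "wt", encoding="ascii") as handle:
        handle.write("row\tcol\tvalue\n")
        for i, j, v in zip(rows, cols, vals):
            handle.write(f"{i}\t{j}\t{v!r}\n")
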