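"""Stage I: pairwise posterior matrices, their combination and distances.

For each unordered pair of sequences two posterior estimates are computed —
one from the 5-state pair-HMM (forward-backward) and one from the
partition function over affine-gap alignments — and merged entrywise as a
root mean square.  A gap-cost-free Needleman-Wunsch pass over the combined
matrix yields the maximum-expected-accuracy score, which defines the
pairwise distance used to build the guide tree.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .params import HmmParams, PartitionParams, encode, wildcard_index
from .sparse_store import (PosteriorMatrix, SparsePosterior, sparsify,
                           transpose)

__all__ = [
    "PosteriorMatrix", "hmm_posterior", "pf_posterior", "combine_rms",
    "mea_score", "mea_matrix", "pair_distance", "posterior_task",
]


def _encode_checked(seq: str, alphabet: str) -> np.ndarray:
    if not seq:
        raise ValueError("sequences must be non-empty")
    codes = encode(seq, alphabet)
    if codes.max() > wildcard_index(alphabet):  # pragma: no cover
        raise ValueError("sequence/alphabet mismatch")
    return codes


def _log(a: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(a > 0.0, np.log(np.where(a > 0.0, a, 1.0)), -np.inf)


def hmm_posterior(x: str, y: str, params: HmmParams,
                  x_id: str = "", y_id: str = "") -> PosteriorMatrix:
    """Pair-HMM match posterior: entry (i, j) = P(x_i ~ y_j | x, y)."""
    cx = _encode_checked(x, params.alphabet)
    cy = _encode_checked(y, params.alphabet)
    if params.match_emit.shape[0] != wildcard_index(params.alphabet) + 1:
        raise ValueError("emission table does not match alphabet")
    post = _kernels.hmm_posterior_kernel(
        cx, cy, _log(params.pi), _log(params.trans),
        _log(params.match_emit), _log(params.ins_emit))
    return PosteriorMatrix(post, x_id=x_id, y_id=y_id)


def pf_posterior(x: str, y: str, params: PartitionParams,
                 x_id: str = "", y_id: str = "") -> PosteriorMatrix:
    """Partition-function match posterior over the Boltzmann ensemble."""
    cx = _encode_checked(x, params.alphabet)
    cy = _encode_checked(y, params.alphabet)
    post = _kernels.pf_posterior_kernel(
        cx, cy, params.beta * params.scores,
        params.beta * params.gap_open, params.beta * params.gap_extend)
    return PosteriorMatrix(post, x_id=x_id, y_id=y_id)


def combine_rms(p_hmm: PosteriorMatrix, p_pf: PosteriorMatrix) -> PosteriorMatrix:
    """Entrywise root mean square sqrt((a^2 + b^2) / 2) of the two posteriors."""
    if p_hmm.shape != p_pf.shape:
        raise ValueError("posterior shapes differ")
    if (p_hmm.x_id, p_hmm.y_id) != (p_pf.x_id, p_pf.y_id):
        raise ValueError("posterior sequence ids differ")
    vals = np.sqrt((p_hmm.values ** 2 + p_pf.values ** 2) / 2.0)
    return PosteriorMatrix(np.minimum(vals, 1.0), x_id=p_hmm.x_id, y_id=p_hmm.y_id)


def mea_matrix(p: np.ndarray) -> np.ndarray:
    """Gap-cost-free Needleman-Wunsch table over a posterior grid.

    M[i][j] = max(M[i-1][j-1] + p[i][j], M[i-1][j], M[i][j-1]); the left
    dependency collapses to a running maximum, so each row is vectorised.
    """
    n_rows, n_cols = p.shape
    m = np.zeros((n_rows, n_cols))
    for i in range(1, n_rows):
        cand = np.maximum(m[i - 1, :-1] + p[i, 1:], m[i - 1, 1:])
        m[i, 1:] = np.maximum.accumulate(cand)
        np.maximum(m[i, 1:], m[i, 0], out=m[i, 1:])
    return m


def mea_score(p: PosteriorMatrix) -> float:
    """Maximum expected accuracy: best total posterior over monotone matchings."""
    return float(mea_matrix(p.values)[-1, -1])


def pair_distance(p: PosteriorMatrix, l_x: int | None = None,
                  l_y: int | None = None) -> float:
    """1 - MEA / min(l_x, l_y), clamped to [0, 1]."""
    if l_x is None:
        l_x = p.shape[0] - 1
    if l_y is None:
        l_y = p.shape[1] - 1
    if (l_x + 1, l_y + 1) != p.shape:
        raise ValueError("lengths inconsistent with posterior shape")
    d = 1.0 - mea_score(p) / min(l_x, l_y)
    return float(min(max(d, 0.0), 1.0))


def posterior_task(x: str, y: str, hmm: HmmParams, pf: PartitionParams,
                   tau: float = 0.01, adaptive_fraction: float | None = None,
                   x_id: str = "", y_id: str = ""
                   ) -> tuple[SparsePosterior, SparsePosterior, float]:
    """Full stage-I task for one pair: sparse S_xy, its transpose S_yx, d_xy.

    Both orientations are returned so the consistency stage can use a single
    multiplication routine over all ordered pairs.  With
    ``adaptive_fraction`` set, the per-matrix top-fraction filter replaces
    the static threshold (accurate mode).
    """
    from .sparse_store import filter_adaptive  # local to keep import cheap

    dense = combine_rms(hmm_posterior(x, y, hmm, x_id, y_id),
                        pf_posterior(x, y, pf, x_id, y_id))
    d_xy = pair_distance(dense, len(x), len(y))
    if adaptive_fraction is not None:
        s_xy = filter_adaptive(sparsify(dense, 0.0), adaptive_fraction)
    else:
        s_xy = sparsify(dense, tau)
    return s_xy, transpose(s_xy), d_xy
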