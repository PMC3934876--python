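"""Shared fixtures and random-instance factories for the suite."""

from __future__ import annotations

import numpy as np
import pytest

from probmsa.params import (AA_ORDER, default_hmm_params,
                            default_partition_params)
from probmsa.sparse_store import PosteriorMatrix, SparsePosterior, sparsify


@pytest.fixture(scope="session")
def hmm_params():
    return default_hmm_params()


@pytest.fixture(scope="session")
def pf_params():
    return default_partition_params()


def random_sequence(rng: np.random.Generator, length: int,
                    alphabet: str = AA_ORDER) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def random_posterior(rng: np.random.Generator, lx: int, ly: int,
                     density: float = 0.5) -> PosteriorMatrix:
    """A random valid dense posterior grid with zero boundary."""
    vals = rng.random((lx + 1, ly + 1))
    vals[rng.random((lx + 1, ly + 1)) > density] = 0.0
    # keep row/column sums inside the single-model bound
    vals /= max(vals.sum(axis=1).max(), vals.sum(axis=0).max(), 1.0)
    vals[0, :] = 0.0
    vals[:, 0] = 0.0
    return PosteriorMatrix(vals)


def random_sparse(rng: np.random.Generator, lx: int, ly: int,
                  density: float = 0.5) -> SparsePosterior:
    return sparsify(random_posterior(rng, lx, ly, density), 0.0)


def random_table(rng: np.random.Generator, lengths: list[int],
                 density: float = 0.7):
    """Random transpose-consistent posterior table over given lengths.

    Returns (PosteriorTable, dict of dense grids for the oracle).
    """
    from probmsa.consistency import PosteriorTable
    from probmsa.sparse_store import densify, transpose

    n = len(lengths)
    upper = {}
    dense = {}
    for x in range(n):
        for y in range(x + 1, n):
            s = random_sparse(rng, lengths[x], lengths[y], density)
            upper[(x, y)] = s
            dense[(x, y)] = densify(s).values
            dense[(y, x)] = dense[(x, y)].T.copy()
    return PosteriorTable.from_upper(n, upper), dense
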