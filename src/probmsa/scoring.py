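"""Sum-of-pairs (SP) and total-column (TC) accuracy against a reference.

SP is the percentage of residue pairs aligned together in the reference
that are also aligned together in the test alignment; TC is the percentage
of reference columns (with at least two residues) whose full residue
content appears together in a single test column.  Gap-residue and gap-gap
pairs are never counted.  When the reference annotates core blocks, scoring
can be restricted to those columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .seqio import Alignment


@dataclass(frozen=True)
class ScoreReport:
    sp: float                # percentage in [0, 100]
    tc: float                # percentage in [0, 100]
    ref_pairs: int           # counted reference residue pairs
    matched_pairs: int
    ref_columns: int         # reference columns with >= 2 residues
    matched_columns: int

    def __post_init__(self):
        if not (0.0 <= self.sp <= 100.0 and 0.0 <= self.tc <= 100.0):
            raise ValueError("scores must lie in [0, 100]")


def _column_maps(aln: Alignment, columns: Optional[Iterable[int]] = None):
    """Per-column dicts name -> 1-based residue index (non-gap cells only)."""
    counters = {name: 0 for name in aln.names}
    out = []
    wanted = set(columns) if columns is not None else None
    for j in range(aln.width):
        col = {}
        for name, row in aln.rows:
            if row[j] != "-":
                counters[name] += 1
                col[name] = counters[name]
        if wanted is None or j in wanted:
            out.append(col)
    return out


def score_alignment(test: Alignment, ref: Alignment,
                    core_columns: Optional[Sequence[int]] = None) -> ScoreReport:
    """SP/TC of ``test`` against ``ref``, optionally restricted to core columns."""
    if set(test.names) != set(ref.names):
        raise ValueError("test and reference contain different sequences")
    test_seqs = dict(test.degapped().records)
    ref_seqs = dict(ref.degapped().records)
    if test_seqs != ref_seqs:
        raise ValueError("test and reference disagree on the unaligned sequences")

    ref_cols = _column_maps(ref, core_columns)
    test_cols = _column_maps(test)

    ref_pairs: set[tuple] = set()
    scored_columns: list[frozenset] = []
    for col in ref_cols:
        items = sorted(col.items())
        if len(items) < 2:
            continue
        scored_columns.append(frozenset(items))
        for a in range(len(items)):
            for b in range(a + 1, len(items)):
                ref_pairs.add((items[a], items[b]))

    test_pairs: set[tuple] = set()
    test_column_sets: set[frozenset] = set()
    for col in test_cols:
        items = sorted(col.items())
        test_column_sets.add(frozenset(items))
        for a in range(len(items)):
            for b in range(a + 1, len(items)):
                test_pairs.add((items[a], items[b]))

    matched_pairs = len(ref_pairs & test_pairs)
    matched_columns = sum(
        1 for col in scored_columns
        if any(col <= tcol for tcol in test_column_sets)
    )
    sp = 100.0 * matched_pairs / len(ref_pairs) if ref_pairs else 0.0
    tc = 100.0 * matched_columns / len(scored_columns) if scored_columns else 0.0
    return ScoreReport(sp=sp, tc=tc,
                       ref_pairs=len(ref_pairs), matched_pairs=matched_pairs,
                       ref_columns=len(scored_columns),
                       matched_columns=matched_columns)


def read_core_mask(path) -> list[int]:
    """Read a core-column mask: whitespace-separated 0-based column indices."""
    with open(path, "rt", encoding="ascii") as handle:
        text = handle.read().split()
    return sorted({int(tok) for tok in text})
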