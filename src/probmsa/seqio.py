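"""Reading, validating and writing sequence sets and alignments.

Sequences live in :class:`SequenceSet` (unaligned, gap-free) and
:class:`Alignment` (gapped rows of identical width).  FASTA is the native
format; CLUSTAL output is available for alignments.  Residues are upper-cased
on input; ``*`` and surrounding whitespace are stripped, and in unaligned mode
the gap characters ``-`` and ``.`` are removed as well (benchmark files mix
conventions).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

AMINO = "amino"
NUCLEOTIDE = "nucleotide"

# Canonical alphabets plus the ambiguity codes accepted on input.  Ambiguous
# amino-acid codes (B, Z, U, O and explicit X) are kept verbatim; scoring
# tables treat everything outside the 20 canonical letters as the wildcard X.
_CANONICAL = {
    AMINO: set("ACDEFGHIKLMNPQRSTVWY"),
    NUCLEOTIDE: set("ACGT"),
}
_AMBIGUOUS = {
    AMINO: set("BZXUO"),
    NUCLEOTIDE: set("NRYSWKMBDHV"),
}
GAP_CHARS = "-."


class FastaFormatError(ValueError):
    """Malformed FASTA input (carries the offending line number)."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def _check_alphabet(alphabet: str) -> None:
    if alphabet not in _CANONICAL:
        raise ValueError(f"unknown alphabet {alphabet!r}")


def valid_residues(alphabet: str) -> frozenset[str]:
    """The set of residue characters accepted for *alphabet*."""
    _check_alphabet(alphabet)
    return frozenset(_CANONICAL[alphabet] | _AMBIGUOUS[alphabet])


@dataclass(frozen=True)
class SequenceSet:
    """An ordered set of named, unaligned residue strings."""

    records: tuple[tuple[str, str], ...]
    alphabet: str = AMINO

    def __post_init__(self):
        _check_alphabet(self.alphabet)
        ok = valid_residues(self.alphabet)
        seen: set[str] = set()
        for name, seq in self.records:
            if not name:
                raise ValueError("empty sequence identifier")
            if name in seen:
                raise ValueError(f"duplicate sequence identifier {name!r}")
            seen.add(name)
            if len(seq) < 1:
                raise ValueError(f"sequence {name!r} is empty")
            bad = set(seq) - ok
            if bad:
                raise ValueError(
                    f"sequence {name!r} contains illegal characters {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.records)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(seq for _, seq in self.records)

    def lengths(self) -> tuple[int, ...]:
        return tuple(len(seq) for _, seq in self.records)


@dataclass(frozen=True)
class Alignment:
    """Gapped rows sharing one width; degapping a row recovers its sequence."""

    rows: tuple[tuple[str, str], ...]
    alphabet: str = AMINO

    def __post_init__(self):
        _check_alphabet(self.alphabet)
        if not self.rows:
            raise ValueError("alignment has no rows")
        widths = {len(seq) for _, seq in self.rows}
        if len(widths) != 1:
            raise ValueError(f"rows have differing widths {sorted(widths)}")
        if self.width == 0:
            raise ValueError("alignment has zero width")
        ok = valid_residues(self.alphabet) | {"-"}
        seen: set[str] = set()
        for name, seq in self.rows:
            if not name:
                raise ValueError("empty sequence identifier")
            if name in seen:
                raise ValueError(f"duplicate sequence identifier {name!r}")
            seen.add(name)
            bad = set(seq) - ok
            if bad:
                raise ValueError(
                    f"row {name!r} contains illegal characters {sorted(bad)}"
                )

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.rows)

    def degapped(self) -> SequenceSet:
        """Strip gaps from every row, recovering the input sequences."""
        return SequenceSet(
            tuple((name, seq.replace("-", "")) for name, seq in self.rows),
            alphabet=self.alphabet,
        )

    def column(self, j: int) -> tuple[str, ...]:
        return tuple(seq[j] for _, seq in self.rows)

    def has_all_gap_column(self) -> bool:
        return any(
            all(seq[j] == "-" for _, seq in self.rows) for j in range(self.width)
        )

    def drop_all_gap_columns(self) -> "Alignment":
        keep = [
            j
            for j in range(self.width)
            if any(seq[j] != "-" for _, seq in self.rows)
        ]
        return Alignment(
            tuple(
                (name, "".join(seq[j] for j in keep)) for name, seq in self.rows
            ),
            alphabet=self.alphabet,
        )


def _parse_fasta(handle: io.TextIOBase, path: str) -> list[tuple[str, str, int]]:
    """Raw FASTA records as (name, residues, header-line-no)."""
    records: list[tuple[str, str, int]] = []
    name: str | None = None
    chunks: list[str] = []
    header_line = 0
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks), header_line))
            name = line[1:].split()[0] if len(line) > 1 and line[1:].split() else ""
            if not name:
                raise FastaFormatError("empty FASTA header", lineno)
            chunks = []
            header_line = lineno
        else:
            if name is None:
                raise FastaFormatError(
                    f"sequence data before first header in {path}", lineno
                )
            chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks), header_line))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def read_fasta(path, alphabet: str = AMINO, aligned: bool = False):
    """Read a FASTA file into a :class:`SequenceSet` or :class:`Alignment`.

    Parameters
    ----------
    path : str or path-like
        FASTA file to read.
    alphabet : {"amino", "nucleotide"}
        Residue alphabet the records are validated against.
    aligned : bool
        If True, gap characters are preserved (``.`` is canonicalised to
        ``-``) and an :class:`Alignment` is returned; otherwise gaps are
        stripped and a :class:`SequenceSet` is returned.
    """
    _check_alphabet(alphabet)
    with open(path, "rt", encoding="ascii") as handle:
        raw = _parse_fasta(handle, str(path))

    cleaned: list[tuple[str, str]] = []
    ok = valid_residues(alphabet) | set(GAP_CHARS)
    for name, seq, lineno in raw:
        seq = seq.upper().replace("*", "")
        bad = set(seq) - ok
        if bad:
            raise FastaFormatError(
                f"record {name!r} contains illegal characters {sorted(bad)}",
                lineno,
            )
        if aligned:
            seq = seq.replace(".", "-")
        else:
            for g in GAP_CHARS:
                seq = seq.replace(g, "")
        if not seq:
            raise FastaFormatError(f"record {name!r} is empty", lineno)
        cleaned.append((name, seq))

    names = [n for n, _ in cleaned]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise FastaFormatError(f"duplicate FASTA identifiers {dup}")

    cls = Alignment if aligned else SequenceSet
    try:
        return cls(tuple(cleaned), alphabet=alphabet)
    except ValueError as exc:  # pragma: no cover - revalidation
        raise FastaFormatError(str(exc)) from exc


def write_fasta(data: SequenceSet | Alignment, path, width: int = 60) -> None:
    """Write *data* as FASTA with 60-column wrapping, rows in input order."""
    rows = data.records if isinstance(data, SequenceSet) else data.rows
    with open(path, "wt", encoding="ascii") as handle:
        for name, seq in rows:
            handle.write(f">{name}\n")
            for start in range(0, len(seq), width):
                handle.write(seq[start : start + width] + "\n")


def write_clustal(aln: Alignment, path, block: int = 60) -> None:
    """Write an alignment in CLUSTAL format (no conservation line)."""
    pad = max(len(name) for name, _ in aln.rows) + 3
    with open(path, "wt", encoding="ascii") as handle:
        handle.write("CLUSTAL multiple sequence alignment\n\n")
        for start in range(0, aln.width, block):
            for name, seq in aln.rows:
                handle.write(name.ljust(pad) + seq[start : start + block] + "\n")
            handle.write("\n")
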