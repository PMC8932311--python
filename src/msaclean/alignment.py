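"""Alignment container, FASTA I/O, alphabet detection and span bookkeeping.

The :class:`Alignment` is the object every cleaning and interpretation
operator consumes and returns: a rectangular matrix of single upper-case
characters over the residue alphabet plus ``'-'`` (the only gap symbol after
normalisation), with ordered, unique sequence names.

Coordinates are 0-based and half-open internally.  Log files written by the
CLI report 0-based *inclusive* column indices; that conversion happens at the
logging layer, never here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"

#: characters counted as nucleotide evidence by :func:`detect_alphabet`
_NT_CHARS = frozenset("ACGTUN")

#: fraction of non-gap cells that must be nucleotide-like for an alignment
#: to be classified as nucleotide.  Tolerates IUPAC ambiguity codes without
#: misclassifying protein sequences (which are mostly non-ACGTUN).
NT_DETECTION_THRESHOLD = 0.7

#: gap dialects normalised to '-' on read
_GAP_DIALECTS = str.maketrans({".": GAP, "~": GAP})

Alphabet = Literal["nucleotide", "amino_acid"]


class AlignmentError(ValueError):
    """Raised for structurally invalid alignment input."""


@dataclass(frozen=True)
class SequenceSpan:
    """Extent of a row's non-gap body: ``[first, last]`` inclusive.

    Gaps outside the span are terminal padding (partial sequences aligned
    against longer ones); gaps inside it are internal and carry alignment
    signal.  For an all-gap row the span is the sentinel ``(-1, -1, 0)``.
    """

    first: int
    last: int
    n_nongap: int

    @property
    def empty(self) -> bool:
        return self.n_nongap == 0

    def covers(self, col: int) -> bool:
        return not self.empty and self.first <= col <= self.last


EMPTY_SPAN = SequenceSpan(-1, -1, 0)


@dataclass
class Alignment:
    """A named, rectangular residue matrix with an alphabet kind.

    Parameters
    ----------
    names:
        Unique sequence identifiers, order-matched to matrix rows.
    matrix:
        2-D array of single characters (dtype ``<U1``); ``'-'`` is the gap.
    alphabet:
        ``"nucleotide"`` or ``"amino_acid"``.
    """

    names: list[str]
    matrix: np.ndarray
    alphabet: Alphabet

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-dimensional")
        if len(self.names) != self.matrix.shape[0]:
            raise AlignmentError(
                f"{len(self.names)} names for {self.matrix.shape[0]} rows"
            )
        seen: set[str] = set()
        for name in self.names:
            if name in seen:
                raise AlignmentError(f"duplicate sequence name: {name!r}")
            seen.add(name)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def row(self, i: int) -> np.ndarray:
        return self.matrix[i]

    def sequence(self, i: int) -> str:
        return "".join(self.matrix[i])

    def gap_mask(self) -> np.ndarray:
        """Boolean matrix, True where the cell is a gap."""
        return self.matrix == GAP

    def take_rows(self, idx: Sequence[int]) -> "Alignment":
        idx = list(idx)
        return Alignment(
            [self.names[i] for i in idx], self.matrix[idx, :], self.alphabet
        )

    def take_cols(self, idx: Sequence[int]) -> "Alignment":
        return Alignment(list(self.names), self.matrix[:, list(idx)], self.alphabet)

    def copy(self) -> "Alignment":
        return Alignment(list(self.names), self.matrix.copy(), self.alphabet)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return (
            self.names == other.names
            and self.alphabet == other.alphabet
            and self.matrix.shape == other.matrix.shape
            and bool((self.matrix == other.matrix).all())
        )


def _normalise(seq: str) -> str:
    return seq.upper().translate(_GAP_DIALECTS)


def alignment_from_sequences(
    names: Iterable[str],
    sequences: Iterable[str],
    alphabet: Alphabet | None = None,
) -> Alignment:
    """Build a normalised Alignment from name/sequence pairs.

    Raises :class:`AlignmentError` on ragged rows or duplicate names; the
    alphabet is auto-detected when not given.
    """
    names = list(names)
    seqs = [_normalise(s) for s in sequences]
    if len(seqs) < 2:
        raise AlignmentError("an alignment requires at least two sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        detail = ", ".join(
            f"{n}:{len(s)}" for n, s in zip(names, seqs)
        )
        raise AlignmentError(
            f"sequences have unequal lengths (not an alignment): {detail}"
        )
    matrix = np.array([list(s) for s in seqs], dtype="<U1")
    aln = Alignment(names, matrix, alphabet or "nucleotide")
    if alphabet is None:
        aln.alphabet = detect_alphabet(aln)
    return aln


def read_fasta(path: str | os.PathLike) -> Alignment:
    """Read a FASTA alignment (>=2 records, equal lengths after gap padding).

    Sequences are upper-cased and gap dialects (``.``, ``~``) mapped to
    ``'-'``; the alphabet is auto-detected.
    """
    records = list(SeqIO.parse(os.fspath(path), "fasta"))
    if len(records) < 2:
        raise AlignmentError(
            f"{path}: alignment requires at least two sequences, found {len(records)}"
        )
    return alignment_from_sequences(
        [r.id for r in records], [str(r.seq) for r in records]
    )


def write_fasta(aln: Alignment, path: str | os.PathLike) -> None:
    """Write the alignment as FASTA, wrapped at 60 columns.

    ``read_fasta(write_fasta(aln))`` reproduces the alignment exactly.
    """
    records = [
        SeqRecord(Seq(aln.sequence(i)), id=aln.names[i], description="")
        for i in range(aln.n_rows)
    ]
    with open(os.fspath(path), "w") as handle:
        SeqIO.write(records, handle, "fasta")


def detect_alphabet(aln: Alignment) -> Alphabet:
    """Classify the alignment as nucleotide or amino acid.

    Nucleotide if the fraction of non-gap cells in ``{A,C,G,T,U,N}`` is at
    least :data:`NT_DETECTION_THRESHOLD`, else amino acid.  Invariant under
    row/column permutation.  An all-gap alignment cannot be classified.
    """
    nongap = aln.matrix[aln.matrix != GAP]
    if nongap.size == 0:
        raise AlignmentError("cannot detect alphabet of an all-gap alignment")
    nt = np.isin(nongap, list(_NT_CHARS)).sum()
    frac = nt / nongap.size
    return "nucleotide" if frac >= NT_DETECTION_THRESHOLD else "amino_acid"


def compute_span(aln: Alignment, row: int) -> SequenceSpan:
    """First/last non-gap column and non-gap count for one row."""
    return span_of_row(aln.matrix[row])


def span_of_row(cells: np.ndarray) -> SequenceSpan:
    nongap = np.flatnonzero(np.asarray(cells, dtype="<U1") != GAP)
    if nongap.size == 0:
        return EMPTY_SPAN
    return SequenceSpan(int(nongap[0]), int(nongap[-1]), int(nongap.size))


def spans(aln: Alignment) -> list[SequenceSpan]:
    """Spans for every row, in row order."""
    return [compute_span(aln, i) for i in range(aln.n_rows)]
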