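"""Alignment summaries: consensus, coverage, similarity, logo statistics.

These are read-only statistics over an :class:`~msaclean.alignment.Alignment`;
none of them modify the alignment.  The pairwise similarity matrix is the
recommended diagnostic before tuning the divergent-sequence threshold.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import entropy

from .alignment import GAP, Alignment, AlignmentError
from .cleaning import consensus_string

ConsensusMode = Literal["majority", "majority_nongap"]

#: alphabet sizes used for logo information content
_ALPHABET_SIZE = {"nucleotide": 4, "amino_acid": 20}


@dataclass(frozen=True)
class ConsensusResult:
    sequence: str
    mode: ConsensusMode


@dataclass(frozen=True)
class CoverageProfile:
    """Per-column proportion of sequences with a non-gap residue."""

    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SimilarityMatrix:
    names: list[str]
    values: np.ndarray

    def lookup(self, a: str, b: str) -> float:
        return float(self.values[self.names.index(a), self.names.index(b)])

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            fh.write("\t" + "\t".join(self.names) + "\n")
            for name, row in zip(self.names, self.values):
                fh.write(name + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")


@dataclass(frozen=True)
class LogoColumn:
    """Information content (bits) and per-residue bar heights of one column.

    ``information_bits`` is log2(alphabet size) minus the Shannon entropy of
    the residue frequencies among the column's non-gap cells (no small-sample
    correction); ``heights`` scales each residue's frequency by that value,
    so the heights sum to the information content.
    """

    information_bits: float
    heights: dict[str, float]


def make_consensus(aln: Alignment, mode: ConsensusMode = "majority_nongap") -> ConsensusResult:
    """Per-column most frequent character.

    ``majority`` counts gaps as characters (but a gap loses frequency ties to
    any residue); ``majority_nongap`` ignores gaps except in all-gap columns.
    Residue-residue ties break alphabetically in both modes.
    """
    if aln.n_rows < 2:
        raise AlignmentError("consensus requires at least two sequences")
    if mode == "majority_nongap":
        return ConsensusResult(consensus_string(aln.matrix), mode)
    if mode != "majority":
        raise ValueError(f"unknown consensus mode: {mode!r}")
    out = []
    for col in range(aln.n_cols):
        column = aln.matrix[:, col]
        chars, counts = np.unique(column, return_counts=True)
        best = counts.max()
        tied = chars[counts == best]
        residues = tied[tied != GAP]
        # gap loses ties; among residues the alphabetically first wins
        out.append(str(residues[0]) if residues.size else GAP)
    return ConsensusResult("".join(out), mode)


def coverage(aln: Alignment) -> CoverageProfile:
    """Fraction of sequences with a non-gap cell, per column."""
    if aln.n_rows < 1:
        raise AlignmentError("coverage requires at least one sequence")
    values = (aln.matrix != GAP).sum(axis=0) / aln.n_rows
    return CoverageProfile(values.astype(float))


def similarity_matrix(aln: Alignment) -> SimilarityMatrix:
    """Pairwise identity over mutually non-gap columns.

    Entry (i, j) is matches / (columns where both rows are non-gap), and 0
    when the two rows share no mutual non-gap column.  Symmetric, with unit
    diagonal for any row with at least one residue.
    """
    if aln.n_rows < 2:
        raise AlignmentError("similarity matrix requires at least two sequences")
    nongap = aln.matrix != GAP
    n = aln.n_rows
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            both = nongap[i] & nongap[j]
            denom = int(both.sum())
            if denom == 0:
                sim = 0.0
            else:
                sim = float((aln.matrix[i, both] == aln.matrix[j, both]).sum() / denom)
            values[i, j] = values[j, i] = sim
    return SimilarityMatrix(list(aln.names), values)


def logo_columns(aln: Alignment, start: int = 0, end: int | None = None) -> list[LogoColumn]:
    """Per-column logo statistics for the window ``[start, end)``.

    For each column, residue frequencies f are taken over non-gap cells and
    the information content is log2(A) - H(f) with A = 4 (nucleotide) or 20
    (amino acid).  An all-gap column carries zero information and renders
    empty.
    """
    end = aln.n_cols if end is None else end
    if not (0 <= start < end <= aln.n_cols):
        raise ValueError(f"invalid logo window [{start}, {end}) for {aln.n_cols} columns")
    max_bits = math.log2(_ALPHABET_SIZE[aln.alphabet])
    out: list[LogoColumn] = []
    for col in range(start, end):
        column = aln.matrix[:, col]
        residues, counts = np.unique(column[column != GAP], return_counts=True)
        if residues.size == 0:
            out.append(LogoColumn(0.0, {}))
            continue
        freqs = counts / counts.sum()
        bits = max_bits - float(entropy(freqs, base=2))
        bits = max(0.0, min(bits, max_bits))  # clamp float error at bounds
        out.append(
            LogoColumn(bits, {str(r): float(f) * bits for r, f in zip(residues, freqs)})
        )
    return out
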