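"""The five alignment-cleaning operators and the fixed-order pipeline.

Each operator is a scikit-learn style transformer over :class:`Alignment`:
``fit(aln)`` decides what to remove and stores the decision in fitted
attributes (``record_`` and friends), ``transform(aln)`` applies it.  The
module-level functions (:func:`remove_divergent`, :func:`remove_insertions`,
:func:`crop_ends`, :func:`remove_short`, :func:`remove_gap_only`,
:func:`run_pipeline`) are thin wrappers kept for script use.

Operators run in a fixed order — divergent rows first (they often carry many
insertions), then insertion columns, then end cropping, with short sequences
removed last since cropping can shorten them — and gap-only column removal is
interleaved after every step by default.  Provenance is tracked per input
cell: the pipeline returns :class:`RemovalRecord` objects and a
:class:`MarkupMap` in which every cell of the *input* alignment is attributed
either to "kept" or to exactly one cleaning function.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .alignment import (
    GAP,
    Alignment,
    AlignmentError,
    SequenceSpan,
    span_of_row,
    spans,
)

FunctionName = Literal[
    "remove_divergent",
    "remove_insertions",
    "crop_ends",
    "remove_short",
    "remove_gap_only",
]

#: execution order of the cleaning functions (gap-only interleaving aside)
PIPELINE_ORDER: tuple[str, ...] = (
    "remove_divergent",
    "remove_insertions",
    "crop_ends",
    "remove_short",
)

ALL_FUNCTIONS: frozenset[str] = frozenset(PIPELINE_ORDER) | {"remove_gap_only"}

#: operators that need three or more sequences to be meaningful
_NEEDS_THREE = frozenset({"remove_divergent", "remove_insertions", "crop_ends"})


class MinimumSequencesError(AlignmentError):
    """An operator was applied to fewer sequences than it requires."""


@dataclass
class CleaningParams:
    """All cleaning thresholds in one validated record.

    Attributes
    ----------
    divergent_min_identity:
        Minimum proportion of a sequence's non-gap positions that must match
        the temporary consensus for the sequence to be kept (default 0.65).
    insertion_min_size, insertion_max_size:
        Width bounds, in columns, for a removable insertion (defaults 3, 200).
    insertion_min_flank:
        Number of non-gap positions required immediately on each side of an
        insertion in the sequences that carry the gap (default 5).
    crop_mingap_prop:
        Gap-count change threshold for end cropping, as a proportion of the
        sequence's non-gap length (default 0.05).
    crop_redefine_prop:
        Proportion of the non-gap length examined at each end when redefining
        the start/end (default 0.1; values above 0.1 are not recommended).
    short_min_length:
        Minimum number of non-gap positions; strictly shorter sequences are
        removed (default 50).
    run_gaponly_after_each_step:
        Interleave gap-only column removal after every cleaning step
        (default True).
    """

    divergent_min_identity: float = 0.65
    insertion_min_size: int = 3
    insertion_max_size: int = 200
    insertion_min_flank: int = 5
    crop_mingap_prop: float = 0.05
    crop_redefine_prop: float = 0.1
    short_min_length: int = 50
    run_gaponly_after_each_step: bool = True

    def __post_init__(self) -> None:
        for name in ("divergent_min_identity", "crop_mingap_prop", "crop_redefine_prop"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.insertion_min_size > self.insertion_max_size:
            raise ValueError(
                "insertion_min_size must not exceed insertion_max_size "
                f"({self.insertion_min_size} > {self.insertion_max_size})"
            )
        for name in ("insertion_min_size", "insertion_max_size",
                     "insertion_min_flank", "short_min_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.crop_redefine_prop > 0.1:
            warnings.warn(
                "crop_redefine_prop above 0.1 may crop genuine sequence "
                "interior; values <= 0.1 are recommended",
                stacklevel=2,
            )


@dataclass
class RemovalRecord:
    """What one cleaning function removed, in INPUT coordinates.

    ``removed_rows`` are sequence names; ``removed_cols`` are whole input
    columns; ``cropped`` maps a sequence name to ``(n_start, n_end)`` counts
    of non-gap cells that were replaced by gaps at each end.  A cell is
    attributed to at most one function across a pipeline run.
    """

    function: str
    removed_rows: list[str] = field(default_factory=list)
    removed_cols: list[int] = field(default_factory=list)
    cropped: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return not (
            self.removed_rows
            or self.removed_cols
            or any(a or b for a, b in self.cropped.values())
        )


# codes used in the markup matrix; 0 is "kept"
MARKUP_LABELS: tuple[str, ...] = (
    "kept",
    "remove_divergent",
    "remove_insertions",
    "crop_ends",
    "remove_short",
    "remove_gap_only",
)
_CODE = {label: i for i, label in enumerate(MARKUP_LABELS)}


@dataclass
class MarkupMap:
    """Per-input-cell attribution: kept, or removed by which function.

    ``codes`` has the dimensions of the input alignment; each cell holds an
    index into :data:`MARKUP_LABELS`.
    """

    codes: np.ndarray

    def label(self, row: int, col: int) -> str:
        return MARKUP_LABELS[self.codes[row, col]]

    def cells_of(self, function: str) -> int:
        """Number of input cells attributed to one function."""
        return int((self.codes == _CODE[function]).sum())

    def n_kept(self) -> int:
        return int((self.codes == 0).sum())

    def counts(self) -> dict[str, int]:
        return {label: int((self.codes == i).sum())
                for i, label in enumerate(MARKUP_LABELS)}


def _require_rows(aln: Alignment, n: int, function: str) -> None:
    if aln.n_rows < n:
        raise MinimumSequencesError(
            f"{function} requires at least {n} sequences, got {aln.n_rows}"
        )


# ---------------------------------------------------------------------------
# temporary consensus (shared with interpretation's majority_nongap mode)
# ---------------------------------------------------------------------------

def temporary_consensus(aln: Alignment) -> str:
    """Per-column most frequent non-gap character.

    All-gap columns yield ``'-'``; frequency ties are broken by alphabetical
    order of the tied residues, which keeps the result deterministic for any
    alphabet.  Requires >= 3 sequences (the consensus of two is arbitrary).
    """
    _require_rows(aln, 3, "temporary_consensus")
    return consensus_string(aln.matrix)


def consensus_string(matrix: np.ndarray) -> str:
    out = []
    for col in range(matrix.shape[1]):
        column = matrix[:, col]
        residues, counts = np.unique(column[column != GAP], return_counts=True)
        if residues.size == 0:
            out.append(GAP)
            continue
        # np.unique sorts residues, so argmax takes the alphabetically
        # first residue among ties
        out.append(str(residues[np.argmax(counts)]))
    return "".join(out)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class _AlignmentCleaner(TransformerMixin, BaseEstimator):
    """Base for single-operator cleaners.

    ``fit`` inspects the alignment and stores the removal decision;
    ``transform`` applies it to the same alignment.
    """

    _function: str = ""

    def _decide(self, aln: Alignment) -> RemovalRecord:  # pragma: no cover
        raise NotImplementedError

    def _apply(self, aln: Alignment) -> Alignment:  # pragma: no cover
        raise NotImplementedError

    def fit(self, X: Alignment, y: None = None) -> "_AlignmentCleaner":
        self.record_ = self._decide(X)
        self.n_rows_in_, self.n_cols_in_ = X.n_rows, X.n_cols
        return self

    def transform(self, X: Alignment) -> Alignment:
        if not hasattr(self, "record_"):
            self.fit(X)
        if (X.n_rows, X.n_cols) != (self.n_rows_in_, self.n_cols_in_):
            raise ValueError(
                "transform input shape differs from the fitted alignment"
            )
        return self._apply(X)

    def fit_transform(self, X: Alignment, y: None = None) -> Alignment:
        return self.fit(X).transform(X)


class RemoveDivergent(_AlignmentCleaner):
    """Drop sequences that poorly match the temporary consensus.

    For each sequence, identity is the proportion of its *non-gap* positions
    that equal the per-column majority consensus; sequences with identity
    below ``min_identity`` are removed.  Using the sequence's own non-gap
    count as denominator avoids penalising partial sequences for terminal
    padding.

    Fitted attributes: ``record_``, ``removed_rows_``, ``identities_``.
    """

    _function = "remove_divergent"

    def __init__(self, min_identity: float = 0.65):
        self.min_identity = min_identity

    def _decide(self, aln: Alignment) -> RemovalRecord:
        _require_rows(aln, 3, self._function)
        cons = np.array(list(consensus_string(aln.matrix)), dtype="<U1")
        nongap = aln.matrix != GAP
        matches = (aln.matrix == cons[None, :]) & nongap
        n_nongap = nongap.sum(axis=1)
        with np.errstate(invalid="ignore"):
            ident = np.where(
                n_nongap > 0, matches.sum(axis=1) / np.maximum(n_nongap, 1), 0.0
            )
        self.identities_ = dict(zip(aln.names, ident.tolist()))
        removed = [aln.names[i] for i in np.flatnonzero(ident < self.min_identity)]
        self.removed_rows_ = removed
        return RemovalRecord(self._function, removed_rows=removed)

    def _apply(self, aln: Alignment) -> Alignment:
        gone = set(self.record_.removed_rows)
        keep = [i for i, n in enumerate(aln.names) if n not in gone]
        return aln.take_rows(keep)


class RemoveInsertions(_AlignmentCleaner):
    """Delete column blocks that are internal gaps in a majority of rows.

    A candidate block is a maximal run of columns where, among rows whose
    non-gap span covers the column, a strict majority have a gap.  Terminal
    gaps (padding outside a row's span) never count as evidence.  The block
    qualifies if its width lies in ``[min_size, max_size]`` and a strict
    majority of covering rows are gapped across the whole block with
    ``min_flank`` non-gap cells in the ``min_flank`` columns immediately
    adjacent on each side.

    Fitted attributes: ``record_``, ``runs_`` (half-open column intervals).
    """

    _function = "remove_insertions"

    def __init__(self, min_size: int = 3, max_size: int = 200, min_flank: int = 5):
        self.min_size = min_size
        self.max_size = max_size
        self.min_flank = min_flank

    def find_runs(self, aln: Alignment) -> list[tuple[int, int]]:
        """Qualifying insertion blocks as half-open ``(start, end)`` pairs."""
        _require_rows(aln, 3, self._function)
        n_rows, n_cols = aln.n_rows, aln.n_cols
        gap = aln.gap_mask()
        row_spans = spans(aln)
        first = np.array([s.first for s in row_spans])
        last = np.array([s.last for s in row_spans])
        nonempty = np.array([not s.empty for s in row_spans])

        cols = np.arange(n_cols)
        covering = (
            nonempty[:, None]
            & (first[:, None] <= cols[None, :])
            & (cols[None, :] <= last[:, None])
        )
        n_cov = covering.sum(axis=0)
        n_gap_internal = (gap & covering).sum(axis=0)
        candidate = (n_cov > 0) & (2 * n_gap_internal > n_cov)

        runs: list[tuple[int, int]] = []
        for start, end in _true_runs(candidate):
            width = end - start
            if not (self.min_size <= width <= self.max_size):
                continue
            if self._run_qualifies(gap, first, last, nonempty, start, end, n_cols):
                runs.append((start, end))
        return runs

    def _run_qualifies(
        self,
        gap: np.ndarray,
        first: np.ndarray,
        last: np.ndarray,
        nonempty: np.ndarray,
        start: int,
        end: int,
        n_cols: int,
    ) -> bool:
        f = self.min_flank
        if start - f < 0 or end + f > n_cols:
            return False  # no room for flanking residues: terminal region
        covers_run = nonempty & (first <= start) & (last >= end - 1)
        if not covers_run.any():
            return False
        gapped = covers_run & gap[:, start:end].all(axis=1)
        flank_ok = (
            (~gap[:, start - f:start]).sum(axis=1) >= f
        ) & ((~gap[:, end:end + f]).sum(axis=1) >= f)
        qualified = gapped & flank_ok
        return 2 * int(qualified.sum()) > int(covers_run.sum())

    def _decide(self, aln: Alignment) -> RemovalRecord:
        self.runs_ = self.find_runs(aln)
        cols = sorted(c for s, e in self.runs_ for c in range(s, e))
        return RemovalRecord(self._function, removed_cols=cols)

    def _apply(self, aln: Alignment) -> Alignment:
        gone = set(self.record_.removed_cols)
        keep = [c for c in range(aln.n_cols) if c not in gone]
        return aln.take_cols(keep)


class CropEnds(_AlignmentCleaner):
    """Redefine ragged sequence starts/ends and gap-mask the crop.

    For each sequence of non-gap length L the first ``floor(redefine_prop*L)``
    non-gap positions are examined (and, mirrored, the last).  The number of
    gap columns between each pair of consecutive examined positions is
    compared with a change threshold of ``max(1, floor(mingap_prop*L))``
    gaps; the sequence start is reset just after the *last* change at least
    that large.  Cells before the new start (after the new end) are replaced
    with gaps — the alignment keeps its shape, rows and columns.

    Fitted attributes: ``record_``, ``new_bounds_`` (per name, (start, end)
    inclusive column indices of the redefined body).
    """

    _function = "crop_ends"

    def __init__(self, mingap_prop: float = 0.05, redefine_prop: float = 0.1):
        self.mingap_prop = mingap_prop
        self.redefine_prop = redefine_prop

    # the two derived quantities of the end-redefinition procedure, kept as
    # methods so scripts can report them for a given sequence length
    def window_size(self, n_nongap: int) -> int:
        """Terminal non-gap positions examined per end for length ``n_nongap``."""
        return math.floor(self.redefine_prop * n_nongap)

    def change_threshold(self, n_nongap: int) -> int:
        """Gap-count change (in gaps) that triggers an end redefinition."""
        return max(1, math.floor(self.mingap_prop * n_nongap))

    def crop_start(self, cells: np.ndarray | str) -> int:
        """New start column (0-based) for one row; unchanged if no crop."""
        cells = _as_cells(cells)
        pos = np.flatnonzero(cells != GAP)
        if pos.size == 0:
            return 0  # all-gap row: nothing to crop
        w = min(self.window_size(pos.size), pos.size)
        if w < 1:
            return int(pos[0])
        thr = self.change_threshold(pos.size)
        window = pos[:w]
        # gaps strictly before each examined position, relative to previous
        gaps_between = np.diff(np.concatenate(([-1], window))) - 1
        hits = np.flatnonzero(gaps_between >= thr)
        if hits.size == 0:
            return int(pos[0])
        return int(window[hits[-1]])

    def crop_end(self, cells: np.ndarray | str) -> int:
        """New end column (0-based inclusive) for one row."""
        cells = _as_cells(cells)
        rev = self.crop_start(cells[::-1])
        return len(cells) - 1 - rev

    def _decide(self, aln: Alignment) -> RemovalRecord:
        _require_rows(aln, 3, self._function)
        cropped: dict[str, tuple[int, int]] = {}
        bounds: dict[str, tuple[int, int]] = {}
        for i, name in enumerate(aln.names):
            row = aln.matrix[i]
            span = span_of_row(row)
            if span.empty:
                continue
            new_start = self.crop_start(row)
            new_end = self.crop_end(row)
            n_start = int((row[span.first:new_start] != GAP).sum())
            n_end = int((row[new_end + 1:span.last + 1] != GAP).sum())
            bounds[name] = (new_start, new_end)
            if n_start or n_end:
                cropped[name] = (n_start, n_end)
        self.new_bounds_ = bounds
        return RemovalRecord(self._function, cropped=cropped)

    def _apply(self, aln: Alignment) -> Alignment:
        out = aln.copy()
        for i, name in enumerate(out.names):
            if name not in self.new_bounds_:
                continue
            start, end = self.new_bounds_[name]
            out.matrix[i, :start] = GAP
            out.matrix[i, end + 1:] = GAP
        return out


class RemoveShort(_AlignmentCleaner):
    """Drop sequences with fewer than ``min_length`` non-gap positions.

    "Fewer than" is strict: a sequence with exactly ``min_length`` residues
    is kept.
    """

    _function = "remove_short"

    def __init__(self, min_length: int = 50):
        self.min_length = min_length

    def _decide(self, aln: Alignment) -> RemovalRecord:
        _require_rows(aln, 2, self._function)
        n_nongap = (aln.matrix != GAP).sum(axis=1)
        removed = [aln.names[i] for i in np.flatnonzero(n_nongap < self.min_length)]
        if len(removed) == aln.n_rows:
            warnings.warn(
                "remove_short removed every sequence; output alignment is empty",
                stacklevel=2,
            )
        return RemovalRecord(self._function, removed_rows=removed)

    def _apply(self, aln: Alignment) -> Alignment:
        gone = set(self.record_.removed_rows)
        keep = [i for i, n in enumerate(aln.names) if n not in gone]
        return aln.take_rows(keep)


class RemoveGapOnly(_AlignmentCleaner):
    """Delete columns that contain only gaps."""

    _function = "remove_gap_only"

    def __init__(self) -> None:
        pass

    def _decide(self, aln: Alignment) -> RemovalRecord:
        all_gap = (aln.matrix == GAP).all(axis=0)
        cols = np.flatnonzero(all_gap).tolist()
        return RemovalRecord(self._function, removed_cols=cols)

    def _apply(self, aln: Alignment) -> Alignment:
        gone = set(self.record_.removed_cols)
        keep = [c for c in range(aln.n_cols) if c not in gone]
        return aln.take_cols(keep)


def _as_cells(cells: np.ndarray | str | Sequence[str]) -> np.ndarray:
    if isinstance(cells, str):
        cells = list(cells)
    return np.asarray(cells, dtype="<U1")


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean vector, as half-open intervals."""
    padded = np.concatenate(([False], mask, [False])).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return list(zip(starts.tolist(), ends.tolist()))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

class CleaningPipeline(TransformerMixin, BaseEstimator):
    """The fixed-order cleaning pipeline with per-cell provenance.

    Runs, among the enabled functions: remove_divergent -> remove_insertions
    -> crop_ends -> remove_short, interleaving gap-only column removal after
    every step when ``params.run_gaponly_after_each_step`` is set.  The order
    is fixed because it affects results: divergent rows are removed first
    (they carry many insertions), short rows last (cropping shortens rows).
    Steps that require three sequences are skipped with a warning on 2-row
    alignments.

    Fitted attributes
    -----------------
    records_ : list of RemovalRecord, all in input coordinates
    markup_ : MarkupMap attributing every input cell
    cleaned_ : the cleaned Alignment
    """

    def __init__(
        self,
        params: CleaningParams | None = None,
        enabled: Iterable[str] | None = None,
    ):
        self.params = params
        self.enabled = enabled

    def _resolved(self) -> tuple[CleaningParams, set[str]]:
        params = self.params if self.params is not None else CleaningParams()
        enabled = set(PIPELINE_ORDER) if self.enabled is None else set(self.enabled)
        unknown = enabled - ALL_FUNCTIONS
        if unknown:
            raise ValueError(f"unknown cleaning function(s): {sorted(unknown)}")
        return params, enabled

    def fit(self, X: Alignment, y: None = None) -> "CleaningPipeline":
        params, enabled = self._resolved()
        cur = X.copy()
        codes = np.zeros((X.n_rows, X.n_cols), dtype=np.int8)
        row_map = np.arange(X.n_rows)  # current row -> input row
        col_map = np.arange(X.n_cols)  # current col -> input col
        records: list[RemovalRecord] = []

        def attribute_rows(names: list[str], code: int) -> None:
            nonlocal cur, row_map
            gone = set(names)
            keep, drop = [], []
            for i, n in enumerate(cur.names):
                (drop if n in gone else keep).append(i)
            for i in drop:
                cells = codes[row_map[i], col_map]
                codes[row_map[i], col_map[cells == 0]] = code
            cur = cur.take_rows(keep)
            row_map = row_map[keep]

        def attribute_cols(removed: list[int], code: int) -> None:
            nonlocal cur, col_map
            gone = set(removed)
            keep = [c for c in range(cur.n_cols) if c not in gone]
            for c in removed:
                cells = codes[row_map, col_map[c]]
                codes[row_map[cells == 0], col_map[c]] = code
            cur = cur.take_cols(keep)
            col_map = col_map[keep]

        def run_gaponly() -> None:
            op = RemoveGapOnly().fit(cur)
            rec = op.record_
            input_cols = [int(col_map[c]) for c in rec.removed_cols]
            attribute_cols(rec.removed_cols, _CODE["remove_gap_only"])
            records.append(
                RemovalRecord("remove_gap_only", removed_cols=input_cols)
            )

        steps = [name for name in PIPELINE_ORDER if name in enabled]
        for name in steps:
            min_rows = 3 if name in _NEEDS_THREE else 2
            if cur.n_rows < min_rows:
                warnings.warn(
                    f"{name} requires at least {min_rows} sequences; skipped "
                    f"on a {cur.n_rows}-sequence alignment",
                    stacklevel=2,
                )
                continue
            if cur.n_cols == 0:
                break
            op = self._make_operator(name, params)
            op.fit(cur)
            rec = op.record_
            if name in ("remove_divergent", "remove_short"):
                records.append(RemovalRecord(name, removed_rows=list(rec.removed_rows)))
                attribute_rows(rec.removed_rows, _CODE[name])
            elif name == "remove_insertions":
                input_cols = [int(col_map[c]) for c in rec.removed_cols]
                records.append(RemovalRecord(name, removed_cols=input_cols))
                attribute_cols(rec.removed_cols, _CODE[name])
            elif name == "crop_ends":
                cropped = {k: v for k, v in rec.cropped.items()}
                records.append(RemovalRecord(name, cropped=cropped))
                # mark masked cells before applying
                name_to_cur = {n: i for i, n in enumerate(cur.names)}
                for seq_name in cropped:
                    i = name_to_cur[seq_name]
                    row = cur.matrix[i]
                    start, end = op.new_bounds_[seq_name]
                    masked = np.flatnonzero(row != GAP)
                    masked = masked[(masked < start) | (masked > end)]
                    for c in masked:
                        if codes[row_map[i], col_map[c]] == 0:
                            codes[row_map[i], col_map[c]] = _CODE["crop_ends"]
                cur = op.transform(cur)
            if params.run_gaponly_after_each_step:
                run_gaponly()

        if "remove_gap_only" in enabled or (
            params.run_gaponly_after_each_step and not steps
        ):
            if not records or records[-1].function != "remove_gap_only":
                run_gaponly()

        self.cleaned_ = cur
        self.records_ = records
        self.markup_ = MarkupMap(codes)
        self.row_map_ = row_map
        self.col_map_ = col_map
        self._fitted_shape = (X.n_rows, X.n_cols)
        return self

    @staticmethod
    def _make_operator(name: str, p: CleaningParams) -> _AlignmentCleaner:
        if name == "remove_divergent":
            return RemoveDivergent(p.divergent_min_identity)
        if name == "remove_insertions":
            return RemoveInsertions(
                p.insertion_min_size, p.insertion_max_size, p.insertion_min_flank
            )
        if name == "crop_ends":
            return CropEnds(p.crop_mingap_prop, p.crop_redefine_prop)
        if name == "remove_short":
            return RemoveShort(p.short_min_length)
        raise ValueError(name)

    def transform(self, X: Alignment) -> Alignment:
        if not hasattr(self, "cleaned_"):
            self.fit(X)
        if (X.n_rows, X.n_cols) != self._fitted_shape:
            raise ValueError("transform input shape differs from fitted alignment")
        return self.cleaned_

    def fit_transform(self, X: Alignment, y: None = None) -> Alignment:
        return self.fit(X).transform(X)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def remove_divergent(
    aln: Alignment, params: CleaningParams | None = None
) -> tuple[Alignment, RemovalRecord]:
    p = params or CleaningParams()
    op = RemoveDivergent(p.divergent_min_identity)
    return op.fit_transform(aln), op.record_


def find_insertions(
    aln: Alignment, params: CleaningParams | None = None
) -> list[tuple[int, int]]:
    p = params or CleaningParams()
    return RemoveInsertions(
        p.insertion_min_size, p.insertion_max_size, p.insertion_min_flank
    ).find_runs(aln)


def remove_insertions(
    aln: Alignment, params: CleaningParams | None = None
) -> tuple[Alignment, RemovalRecord]:
    p = params or CleaningParams()
    op = RemoveInsertions(
        p.insertion_min_size, p.insertion_max_size, p.insertion_min_flank
    )
    return op.fit_transform(aln), op.record_


def crop_end(
    row_cells: np.ndarray | str | Sequence[str],
    params: CleaningParams | None = None,
    side: Literal["start", "end"] = "start",
) -> int:
    """New start (or inclusive end) column index for a single row."""
    p = params or CleaningParams()
    op = CropEnds(p.crop_mingap_prop, p.crop_redefine_prop)
    return op.crop_start(row_cells) if side == "start" else op.crop_end(row_cells)


def crop_ends(
    aln: Alignment, params: CleaningParams | None = None
) -> tuple[Alignment, RemovalRecord]:
    p = params or CleaningParams()
    op = CropEnds(p.crop_mingap_prop, p.crop_redefine_prop)
    return op.fit_transform(aln), op.record_


def remove_short(
    aln: Alignment, params: CleaningParams | None = None
) -> tuple[Alignment, RemovalRecord]:
    p = params or CleaningParams()
    op = RemoveShort(p.short_min_length)
    return op.fit_transform(aln), op.record_


def remove_gap_only(aln: Alignment) -> tuple[Alignment, RemovalRecord]:
    op = RemoveGapOnly()
    return op.fit_transform(aln), op.record_


def run_pipeline(
    aln: Alignment,
    params: CleaningParams | None = None,
    enabled: Iterable[str] | None = None,
) -> tuple[Alignment, list[RemovalRecord], MarkupMap]:
    pipe = CleaningPipeline(params=params, enabled=enabled).fit(aln)
    return pipe.cleaned_, pipe.records_, pipe.markup_
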