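"""Deterministic synthetic alignments with planted, ground-truthed defects.

The generator emulates the defect classes the cleaning operators target: a
backbone of near-identical sequences (point substitutions at a low rate)
into which it plants divergent rows, minority-carried internal insertions,
ragged gap-scattered sequence ends, very short fragments, and all-gap
columns.  Each planted defect comes with an arithmetically derived ground
truth of what the corresponding cleaning operator should do, so operators
are testable without any external data.

Plans are validated on construction: defects that would interact in ways
that make the truth ambiguous (an insertion inside a ragged-end window, a
gap-only column between scattered end residues, carriers forming a majority)
are rejected with an error listing every conflict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .alignment import GAP, Alignment
from .cleaning import CleaningParams

_NT = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: backbone substitution rate per cell; low enough that backbone rows stay
#: far above any sensible divergence threshold
MUTATION_RATE = 0.02


@dataclass(frozen=True)
class Insertion:
    start: int
    width: int
    carrier_rows: tuple[int, ...]

    @property
    def end(self) -> int:
        return self.start + self.width


@dataclass(frozen=True)
class RaggedEnd:
    row: int
    side: Literal["start", "end"]
    n_scattered: int
    gap_spread: int

    def region_width(self) -> int:
        # gap_spread gaps before each scattered residue and after the last
        return self.n_scattered * (self.gap_spread + 1) + self.gap_spread


@dataclass
class DefectPlan:
    """Recipe for one synthetic alignment; same seed, same output."""

    n_rows: int = 6
    n_cols: int = 120
    alphabet: Literal["nucleotide", "amino_acid"] = "nucleotide"
    divergent_rows: list[tuple[int, float]] = field(default_factory=list)
    insertions: list[Insertion] = field(default_factory=list)
    ragged_ends: list[RaggedEnd] = field(default_factory=list)
    short_rows: list[tuple[int, int]] = field(default_factory=list)
    gaponly_cols: list[int] = field(default_factory=list)
    seed: int = 0


@dataclass
class GroundTruth:
    """What each cleaning operator should do to the planted alignment.

    ``insertion_runs`` holds every planted block with a flag saying whether
    it qualifies for removal under the plan's parameters (width in bounds);
    ``cropped`` gives the exact per-end masked-residue counts crop-ends
    should produce; row lists are sequence names.
    """

    divergent_rows: dict[str, float] = field(default_factory=dict)
    insertion_runs: list[tuple[int, int, bool]] = field(default_factory=list)
    cropped: dict[str, tuple[int, int]] = field(default_factory=dict)
    short_rows: list[str] = field(default_factory=list)
    gaponly_cols: list[int] = field(default_factory=list)


def _row_name(i: int) -> str:
    return f"seq{i}"


def _validate(plan: DefectPlan, params: CleaningParams) -> None:
    errors: list[str] = []
    special_rows: dict[int, str] = {}

    def claim(row: int, kind: str) -> None:
        if row in special_rows:
            errors.append(
                f"row {row} is both {special_rows[row]} and {kind}; "
                "planted truth would be ambiguous"
            )
        elif not 0 <= row < plan.n_rows:
            errors.append(f"{kind} row {row} outside 0..{plan.n_rows - 1}")
        else:
            special_rows[row] = kind

    for row, ident in plan.divergent_rows:
        claim(row, "divergent")
        if not 0 < ident < 1:
            errors.append(f"divergent target identity {ident} not in (0, 1)")
    for row, n in plan.short_rows:
        claim(row, "short")
        if n <= 0 or n >= plan.n_cols:
            errors.append(f"short row length {n} not in 1..{plan.n_cols - 1}")
    for r in plan.ragged_ends:
        claim(r.row, "ragged")
        if r.region_width() >= plan.n_cols // 2:
            errors.append(f"ragged region of row {r.row} spans half the alignment")

    flank = params.insertion_min_flank
    ragged_regions = [
        (0, r.region_width()) if r.side == "start"
        else (plan.n_cols - r.region_width(), plan.n_cols)
        for r in plan.ragged_ends
    ]
    for ins in plan.insertions:
        lo, hi = ins.start - flank, ins.end + flank
        if lo < 0 or hi > plan.n_cols:
            errors.append(
                f"insertion at {ins.start} has no room for a {flank}-column flank"
            )
        if 2 * len(ins.carrier_rows) >= plan.n_rows:
            errors.append(
                f"insertion at {ins.start}: carriers must be a strict minority"
            )
        for rl, rh in ragged_regions:
            if lo < rh and rl < hi:
                errors.append(
                    f"insertion at {ins.start} overlaps a ragged-end window"
                )
        for col in plan.gaponly_cols:
            if lo <= col < hi:
                errors.append(
                    f"gap-only column {col} inside insertion/flank [{lo}, {hi})"
                )
        for row in ins.carrier_rows:
            if special_rows.get(row) in ("short", "ragged", "divergent"):
                errors.append(
                    f"insertion carrier row {row} is also {special_rows[row]}"
                )
    for a in plan.insertions:
        for b in plan.insertions:
            if a is not b and a.start < b.end + flank and b.start < a.end + flank:
                errors.append(
                    f"insertions at {a.start} and {b.start} closer than one flank"
                )
                break
    for col in plan.gaponly_cols:
        if not 0 <= col < plan.n_cols:
            errors.append(f"gap-only column {col} outside the alignment")
        for rl, rh in ragged_regions:
            if rl <= col < rh:
                errors.append(f"gap-only column {col} inside a ragged-end window")
    if errors:
        raise ValueError("invalid defect plan:\n  " + "\n  ".join(sorted(set(errors))))


def generate(
    plan: DefectPlan, params: CleaningParams | None = None
) -> tuple[Alignment, GroundTruth]:
    """Realise a plan into an alignment plus per-operator ground truth.

    The truth is derived arithmetically from the plan under ``params``
    (defaults used when omitted), independently of the cleaning operators.
    """
    params = params or CleaningParams()
    _validate(plan, params)
    rng = np.random.default_rng(plan.seed)
    residues = _NT if plan.alphabet == "nucleotide" else _AA

    base = residues[rng.integers(0, residues.size, plan.n_cols)]
    matrix = np.tile(base, (plan.n_rows, 1)).astype("<U1")
    mut_mask = rng.random(matrix.shape) < MUTATION_RATE
    shifts = rng.integers(1, residues.size, matrix.shape)
    idx_of = {c: i for i, c in enumerate(residues)}
    base_idx = np.array([idx_of[c] for c in base])
    mutated = residues[(base_idx[None, :] + shifts) % residues.size]
    matrix[mut_mask] = mutated[mut_mask]

    truth = GroundTruth(gaponly_cols=sorted(plan.gaponly_cols))

    for ins in plan.insertions:
        carriers = set(ins.carrier_rows)
        for row in range(plan.n_rows):
            if row not in carriers:
                matrix[row, ins.start:ins.end] = GAP
        qualifies = (
            params.insertion_min_size <= ins.width <= params.insertion_max_size
        )
        truth.insertion_runs.append((ins.start, ins.end, qualifies))

    for col in plan.gaponly_cols:
        matrix[:, col] = GAP

    for row, n in plan.short_rows:
        keep = _short_segment(matrix[row], n, plan, params)
        cells = matrix[row].copy()
        matrix[row, :] = GAP
        matrix[row, keep] = cells[keep]
        truth.short_rows.append(_row_name(row))

    for r in plan.ragged_ends:
        _plant_ragged(matrix, r, residues, rng)

    for row, target in plan.divergent_rows:
        _plant_divergent(matrix, row, target, base, residues, rng)
        truth.divergent_rows[_row_name(row)] = target

    names = [_row_name(i) for i in range(plan.n_rows)]
    aln = Alignment(names, matrix, plan.alphabet)

    # crop-ends truth needs the final per-row non-gap lengths
    for r in plan.ragged_ends:
        L = int((matrix[r.row] != GAP).sum())
        window = math.floor(params.crop_redefine_prop * L)
        threshold = max(1, math.floor(params.crop_mingap_prop * L))
        if r.gap_spread < threshold or r.n_scattered >= window:
            raise ValueError(
                f"ragged end on row {r.row}: gap_spread {r.gap_spread} below the "
                f"change threshold {threshold} or {r.n_scattered} scattered "
                f"residues not inside the {window}-position window (L={L})"
            )
        n_start, n_end = (r.n_scattered, 0) if r.side == "start" else (0, r.n_scattered)
        prev = truth.cropped.get(_row_name(r.row), (0, 0))
        truth.cropped[_row_name(r.row)] = (prev[0] + n_start, prev[1] + n_end)

    return aln, truth


def _short_segment(
    cells: np.ndarray, n: int, plan: DefectPlan, params: CleaningParams
) -> np.ndarray:
    """Contiguous run of n currently non-gap columns for the short fragment."""
    nongap = np.flatnonzero(cells != GAP)
    runs = np.split(nongap, np.flatnonzero(np.diff(nongap) > 1) + 1)
    for run in runs:
        if run.size >= n:
            off = (run.size - n) // 2
            return run[off:off + n]
    raise ValueError(
        f"no contiguous stretch of {n} non-gap columns available for a short row"
    )


def _plant_ragged(
    matrix: np.ndarray, r: RaggedEnd, residues: np.ndarray, rng: np.random.Generator
) -> None:
    width = r.region_width()
    n_cols = matrix.shape[1]
    region = np.full(width, GAP, dtype="<U1")
    pos = [(k + 1) * r.gap_spread + k for k in range(r.n_scattered)]
    region[pos] = residues[rng.integers(0, residues.size, r.n_scattered)]
    if r.side == "start":
        matrix[r.row, :width] = region
    else:
        matrix[r.row, n_cols - width:] = region[::-1]


def _plant_divergent(
    matrix: np.ndarray,
    row: int,
    target: float,
    base: np.ndarray,
    residues: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Reset the row to the backbone, then flip cells to miss the consensus.

    With the other rows near-identical the column consensus equals the
    backbone character, so identity lands on the target up to rounding.
    """
    nongap = np.flatnonzero(matrix[row] != GAP)
    matrix[row, nongap] = base[nongap]
    k = round((1.0 - target) * nongap.size)
    flip = rng.choice(nongap, size=k, replace=False)
    idx_of = {c: i for i, c in enumerate(residues)}
    for col in flip:
        matrix[row, col] = residues[(idx_of[str(base[col])] + 1) % residues.size]


def example1_like() -> tuple[Alignment, GroundTruth]:
    """A small toy alignment showing all five defect classes at once.

    Six nucleotide sequences, ~120 columns: one highly divergent row, one
    4-column insertion carried by a single sequence, one ragged gap-scattered
    start, one 10-residue fragment and two all-gap columns.  Intended for
    end-to-end smoke tests of the full pipeline.
    """
    plan = DefectPlan(
        n_rows=6,
        n_cols=120,
        alphabet="nucleotide",
        divergent_rows=[(1, 0.45)],
        insertions=[Insertion(60, 4, (0,))],
        ragged_ends=[RaggedEnd(3, "start", 2, 6)],
        short_rows=[(4, 10)],
        gaponly_cols=[30, 95],
        seed=17,
    )
    return generate(plan)
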