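# Methods

## Scope and data model

`msaclean` operates on a pre-computed multiple sequence alignment: a
rectangular matrix of single characters over a residue alphabet plus the gap
symbol `-`, with at least two uniquely named sequences. On read, sequences
are upper-cased and the gap dialects `.` and `~` are normalised to `-`;
ragged rows and duplicate names are rejected rather than repaired. The
alphabet is auto-detected: if at least 70% of non-gap cells fall in
`{A,C,G,T,U,N}` the alignment is treated as nucleotide, otherwise as amino
acid. The 70% cut-off is our choice — it tolerates IUPAC ambiguity codes in
DNA without misclassifying protein, whose residues are mostly outside that
set. Coordinates are 0-based and half-open internally; log files use
0-based inclusive column indices, stated in their headers.

A sequence's *span* is the closed interval from its first to last non-gap
cell. Gaps outside the span are terminal padding (as arise when aligning
overlapping partial sequences) and are deliberately ignored wherever gaps
are used as evidence of misalignment; only internal gaps count.

## Cleaning operators

All thresholds live in `CleaningParams`; defaults below.

**remove_divergent** (threshold 0.65, proportion). A temporary consensus
takes each column's most frequent non-gap residue (all-gap columns give
`-`). Frequency ties break by alphabetical order of the tied residues — an
arbitrary but deterministic rule that works for both alphabets. Each
sequence's identity is the fraction of its *own* non-gap positions matching
the consensus; the sequence's non-gap count is the denominator so partial
sequences are not penalised for padding. An all-gap row has identity 0 and
is removed. The consensus is computed once per invocation, not re-derived
after each removal. Requires ≥ 3 sequences.

**remove_insertions** (width 3–200 columns, flank 5 positions). Candidate
columns are those where a strict majority (> 50%) of covering sequences —
sequences whose span includes the column — hold a gap; terminal gaps are
excluded from numerator and denominator. Maximal runs of candidate columns
whose width is within bounds qualify if, among the sequences covering the
whole run, a strict majority are gapped across the entire run *and* have
all 5 flanking positions non-gap on each side. A run too close to the
alignment edge to fit its flank never qualifies. Qualifying columns are
deleted for every sequence. The covering-rows denominator and the
application of the flank test to the gapped sequences are our readings of
the insertion definition; both are fixed here and exercised by the oracle
tests. Requires ≥ 3 sequences.

**crop_ends** (gap-change proportion 0.05, window proportion 0.1). For a
sequence of non-gap length ℓ, the window is `w = ⌊0.1 ℓ⌋` terminal non-gap
positions per side and the change threshold is `t = max(1, ⌊0.05 ℓ⌋)` gaps
(for ℓ = 80: w = 8 and t = 4). Walking the first w non-gap positions
p₁…p_w, with d₀ the gaps before p₁ and dᵢ the gaps strictly between pᵢ and
pᵢ₊₁, the start is redefined to pᵢ₊₁ for the *largest* i with dᵢ ≥ t; the
end side mirrors this on the reversed sequence. The comparison is ≥, and
`max(1, ·)` keeps short sequences from getting a zero threshold. Cropped
residues are replaced by gaps — the matrix shape is preserved, and the
per-side masked count can never exceed w. Window proportions above 0.1 are
accepted with a warning: beyond that point long gaps are unlikely to mark
an incomplete end. Requires ≥ 3 sequences.

**remove_short** (minimum 50 non-gap positions). Strictly-fewer-than
semantics: 49 residues are removed, 50 kept. Runs last because cropping can
shorten sequences.

**remove_gap_only**. Deletes columns that are entirely gaps. Interleaved
after every enabled step by default (`run_gaponly_after_each_step`), since
each of the other operators can create such columns.

### Pipeline order and provenance

The fixed order — divergent, insertions, crop ends, short — matters:
divergent sequences typically carry many insertions, so removing them first
keeps later work minimal, and shortened sequences must be measured after
cropping. The pipeline is not user-reorderable. Steps requiring three
sequences are skipped with a warning on two-sequence input rather than
aborting.

Provenance is maintained through a live old→new index map: every removal
record is expressed in input coordinates, and a markup matrix assigns each
input cell exactly one label (kept, or the operator that removed it). A
cropped cell keeps its `crop_ends` label even if its column is later
deleted as gap-only — attribution is first-touch and unique, which makes
the accounting identity `input cells = kept + Σ per-operator cells` hold
exactly; the test suite checks it on every pipeline run it performs.

## Interpretation

The consensus ships in two modes: `majority_nongap` (identical to the
cleaning consensus — a single shared implementation) and `majority`, where
gaps compete on frequency but lose ties to residues. Coverage is the
per-column non-gap fraction. The similarity matrix is pairwise identity
over mutually non-gap columns, 0 when a pair shares none — the same
partial-sequence philosophy as the divergence identity; it is the
recommended diagnostic before tuning the divergence threshold. Logo columns
use the classical information-content formulation `IC = log₂A − H` with
A = 4 or 20 and frequencies over non-gap cells only, with no small-sample
correction (simplest standard form; a correction could be added as a flag).
An all-gap column carries 0 bits and renders empty.

## Visualisation

Mini alignments build an RGB array with one pixel per cell and display it
with `imshow`, stretched to the axes — memory and time stay flat in
alignment size. Default palettes are conventional (A green, C blue, G
orange, T/U red, N grey, gap white; amino acids coloured by physicochemical
class) and fully overridable via `RenderSpec.palette`; a character without
a colour raises an error naming it. Markup plots over-paint removed cells
with one distinct hue per operator plus a legend; the overlay pixel count
equals the markup attribution count by construction and by test. Logos
above `max_logo_columns` (default 500) are refused with a clear error to
stay under renderer pixel limits; mini alignments are exempt because they
use the image path. Output formats are PNG, SVG and TIFF; for a fixed spec
the bytes are reproducible across runs on one platform (SVG date metadata
is suppressed for this).

## Command line

The input path is the only mandatory parameter; every function runs only if
requested. `all` enables everything; `clean` enables the cleaning functions
only; `visualise`/`interpret` enable their groups — we read the meta-flag
names literally where their prose descriptions overlap. Flags may be given
with or without leading dashes. A flat `key=value` file (`inifile`)
supplies defaults under command-line precedence. Each run writes the
cleaned FASTA, a log (timestamp, full parameter block, per-step counts) and
a removed-items table; the parameter block parses back into an identical
configuration, and a re-run from it reproduces the outputs byte for byte.
On error, partially written outputs are deleted.

## Synthetic data generator

The generator (`msaclean.synthetic`) emulates the defect classes the
operators target, on a backbone of near-identical sequences: a random base
sequence copied to every row with point substitutions at 2% per cell — low
enough that backbone rows sit far above any sensible divergence threshold,
high enough that rows are distinguishable. Planted defects are realised
exactly:

- *divergent rows*: the row is reset to the base sequence, then a computed
  number of its non-gap cells is flipped to a non-consensus residue, so its
  consensus identity equals the target up to rounding;
- *insertions*: a column block where only the (strict-minority) carrier
  rows keep residues;
- *ragged ends*: scattered residues separated by gap runs at least as wide
  as the crop-ends change threshold, placed inside the examination window;
- *short rows*: a contiguous backbone fragment of the requested length;
- *gap-only columns*: set directly.

Plans are validated on construction and conflicting plants (an insertion in
a ragged window, carriers in the majority, a gap-only column between
scattered end residues) are rejected with all conflicts listed, so every
plan's ground truth is unambiguous and derived arithmetically, independent
of the operators. Generation is seeded and deterministic.

What the generator does *not* emulate: realistic substitution models or
rate heterogeneity, indel length distributions, sequencing error profiles,
or phylogenetic correlation between sequences. Tests passing on these
fixtures demonstrate that the operators implement their definitions exactly
and recover cleanly planted defects; they do not measure over- or
under-trimming on real, messy alignments, where defects interact and
thresholds trade off.

## Test and verification strategy

Every operator is checked three ways: hand-built boundary examples (the
80-residue crop-ends arithmetic, the 49/50 short-sequence boundary,
insertion widths straddling 3 and 200), equivalence against independently
coded brute-force oracles on hundreds of small random alignments (≤ 12×40,
500 trials), and planted-defect recovery through the generator. Pipeline
runs additionally verify the cell-partition identity, record/markup
reconciliation and determinism on 200 mixed fixtures. Problem sizes were
chosen so the whole suite runs in well under a minute on one core while the
oracle comparisons still cover the operators' combinatorics.

## Known limitations

- The divergence consensus is not recomputed between removals; an extreme
  outlier block could in principle shift the consensus before removal.
- Insertion detection treats each qualifying run independently; adjacent
  runs separated by a single non-candidate column are not merged.
- Similarity is raw identity, not distance-corrected.
- Two-sequence alignments only support short-sequence and gap-only
  cleaning.
- Image reproducibility is guaranteed per platform/matplotlib version, not
  across versions.
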