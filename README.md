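# msaclean

Transparent cleaning, visualisation and interpretation of multiple sequence
alignments (MSAs).

## The problem

Automatically generated MSAs — of transcripts, genes or genome segments —
routinely contain defects that disrupt downstream analysis: one or a few
highly divergent sequences that align poorly against the rest; large gap
blocks carried by a minority of sequences (insertions in a few, or missing
data); unreliably aligned, gap-scattered sequence starts and ends; fragments
too short to align confidently; and columns that contain nothing but gaps.
Column-masking trimmers work column-by-column and cannot remove divergent
*rows*, and most tools do not report exactly what they changed.

`msaclean` removes each of these defect classes with a dedicated operator,
distinguishes internal gaps (alignment signal) from terminal gaps (padding of
partial sequences), and logs every removed sequence, column and cropped
position so a run can be reported and reproduced exactly.

## The operators

Given an alignment of `N` sequences and `L` columns with gap character `-`:

- **remove_divergent** — build a temporary consensus (per-column majority
  residue) and drop every sequence whose identity to it, over the sequence's
  own non-gap positions, is below a threshold `p` (default `p = 0.65`).
- **remove_insertions** — delete maximal column blocks in which a strict
  majority of *covering* sequences (those whose non-gap span includes the
  column) carry an internal gap, provided the block width lies in
  `[3, 200]` columns and the gapped sequences have ≥ 5 non-gap positions in
  the 5 columns flanking each side. Terminal gaps never count as evidence.
- **crop_ends** — per sequence of non-gap length `ℓ`, examine the first and
  last `⌊0.1 ℓ⌋` non-gap positions; wherever the gap count between two
  consecutive examined positions is ≥ `max(1, ⌊0.05 ℓ⌋)`, the sequence
  start/end is redefined past the last such change and the cropped residues
  are replaced by gaps (the alignment keeps its shape).
- **remove_short** — drop sequences with fewer than 50 non-gap positions
  (strictly fewer: exactly 50 is kept).
- **remove_gap_only** — delete all-gap columns; run after every other step
  by default.

The operators run in the fixed order above; each returns a reduced alignment
plus a removal record in input coordinates, and the pipeline produces a
per-cell markup attributing every input cell to "kept" or to exactly one
operator. Interpretation utilities compute consensus sequences (majority and
non-gap majority), per-column coverage, a pairwise identity matrix over
mutually non-gap columns, and per-column logo information content
`IC = log₂A − H` (A = 4 or 20). Visualisation renders mini alignments (one
image cell per residue), markup plots with a colour per operator, coverage
plots, and sequence logos in letter or rectangle style.

The cleaning operators are scikit-learn style transformers
(`RemoveDivergent`, `RemoveInsertions`, `CropEnds`, `RemoveShort`,
`RemoveGapOnly`, `CleaningPipeline`) with `fit`/`transform`, `get_params`
and fitted attributes (`record_`, `markup_`, `cleaned_`), and compose with
`sklearn.pipeline.Pipeline`; module-level functions wrap them for script
use.

## Worked example

```python
from msaclean.synthetic import example1_like
from msaclean.alignment import write_fasta

aln, truth = example1_like()       # 6 x 120 toy with all five defect classes
write_fasta(aln, "example.fasta")
```

```bash
msaclean infile example.fasta outfile_stem demo all
cat demo_removed.txt
```

```
function	removed_sequences	removed_columns	cropped
crop_ends			seq3:2:0
remove_divergent	seq1		
remove_gap_only		30,95	
remove_insertions		60,61,62,63	
remove_short	seq4		
```

Reading the table: the divergent sequence `seq1` (planted at 45% consensus
identity, below the 0.65 default) was removed whole; the 4-column insertion
block at columns 60–63 (carried by one of six sequences) was deleted for all
rows; 2 gap-scattered leading residues of `seq3` were cropped
(`name:start:end` counts); the 10-residue fragment `seq4` fell below the
50-residue minimum; and the two all-gap columns 30 and 95 were dropped. The
run log ends with:

```
input: 6 sequences x 120 columns
output: 4 sequences x 114 columns
```

and `demo_markup.png` shows the input alignment with each removed region in
the colour of the operator that removed it. Column indices are 0-based, in
input coordinates. Re-running with the `[parameters]` block of
`demo_log.txt` (see `msaclean.cli.config_from_log`) reproduces the outputs
byte for byte.

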