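"""Mini alignments, markup plots, coverage plots and sequence logos.

A mini alignment renders each alignment cell as one pixel of an image array
shown with matplotlib's ``imshow`` and stretched to the axes, which keeps
memory and time flat even for large alignments.  The markup plot draws the
*input* alignment and over-paints every removed cell with the colour of the
cleaning function that removed it, with a legend.  Logos come in the
traditional letter style and a rectangle style that stays readable in poorly
conserved regions.

Rendering never mutates its inputs and, for a fixed spec, produces identical
files across runs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Literal, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import to_rgb
from matplotlib.font_manager import FontProperties
from matplotlib.patches import PathPatch, Patch, Rectangle
from matplotlib.textpath import TextPath
from matplotlib.transforms import Affine2D

from .alignment import GAP, Alignment
from .cleaning import MARKUP_LABELS, MarkupMap
from .interpretation import CoverageProfile, LogoColumn

#: nucleotide palette (conventional base colours; ambiguity codes grey)
NUCLEOTIDE_PALETTE: dict[str, str] = {
    "A": "#2ca02c",  # green
    "C": "#1f77b4",  # blue
    "G": "#ff7f0e",  # orange
    "T": "#d62728",  # red
    "U": "#d62728",
    "N": "#7f7f7f",
    **{c: "#b0b0b0" for c in "RYSWKMBDHV"},
    GAP: "#ffffff",
}

#: amino-acid palette grouped by physicochemical class
AMINO_ACID_PALETTE: dict[str, str] = {
    # small / hydrophobic — greens
    "A": "#4daf4a", "V": "#6abf69", "L": "#3d8b40", "I": "#81c784",
    "M": "#2e7d32", "G": "#a5d6a7", "P": "#c8e6c9",
    # aromatic — purples
    "F": "#984ea3", "W": "#7b1fa2", "Y": "#ba68c8",
    # polar uncharged — blues
    "S": "#64b5f6", "T": "#1e88e5", "N": "#90caf9", "Q": "#1565c0",
    "C": "#00acc1",
    # positively charged — reds
    "K": "#e53935", "R": "#b71c1c", "H": "#ef9a9a",
    # negatively charged — oranges
    "D": "#fb8c00", "E": "#ef6c00",
    # ambiguity / stops
    "X": "#7f7f7f", "B": "#b0b0b0", "Z": "#b0b0b0", "J": "#b0b0b0",
    "*": "#000000",
    GAP: "#ffffff",
}

#: one distinct hue per cleaning function for markup overlays
MARKUP_PALETTE: dict[str, str] = {
    "remove_divergent": "#e41a1c",
    "remove_insertions": "#377eb8",
    "crop_ends": "#ff7f00",
    "remove_short": "#984ea3",
    "remove_gap_only": "#999999",
}


class PaletteError(KeyError):
    """A character in the alignment has no colour in the palette."""


@dataclass
class RenderSpec:
    """Output parameters shared by all renderers.

    ``palette`` of None selects the default palette for the alignment's
    alphabet.  ``max_logo_columns`` guards the letter-drawing path against
    renderer pixel limits on very wide windows; mini alignments are exempt
    (they go through the image-array path).
    """

    width: float = 10.0
    height: float = 5.0
    dpi: int = 150
    format: Literal["png", "svg", "tiff"] = "png"
    palette: dict[str, str] | None = None
    markup_palette: dict[str, str] = field(default_factory=lambda: dict(MARKUP_PALETTE))
    max_logo_columns: int = 500

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.dpi <= 0:
            raise ValueError("RenderSpec dimensions and dpi must be positive")
        if self.format not in ("png", "svg", "tiff"):
            raise ValueError(f"unsupported image format: {self.format!r}")

    def palette_for(self, aln: Alignment) -> dict[str, str]:
        if self.palette is not None:
            return self.palette
        return NUCLEOTIDE_PALETTE if aln.alphabet == "nucleotide" else AMINO_ACID_PALETTE


def build_rgb(aln: Alignment, palette: dict[str, str]) -> np.ndarray:
    """(n_rows, n_cols, 3) float RGB array, one pixel per alignment cell."""
    chars = np.unique(aln.matrix)
    missing = [c for c in chars if c not in palette]
    if missing:
        raise PaletteError(
            f"palette has no colour for character(s): {', '.join(missing)}"
        )
    lut = {c: to_rgb(palette[c]) for c in chars}
    rgb = np.empty((aln.n_rows, aln.n_cols, 3), dtype=float)
    for c, colour in lut.items():
        rgb[aln.matrix == c] = colour
    return rgb


def _save(fig: plt.Figure, path: str | os.PathLike, spec: RenderSpec) -> None:
    metadata = {"Date": None} if spec.format == "svg" else None
    fig.savefig(os.fspath(path), format=spec.format, dpi=spec.dpi, metadata=metadata)
    plt.close(fig)


def _mini_axes(fig: plt.Figure, rgb: np.ndarray) -> plt.Axes:
    ax = fig.add_subplot(111)
    ax.imshow(rgb, aspect="auto", interpolation="nearest")
    ax.set_xlabel("alignment column")
    ax.set_ylabel("sequence")
    return ax


def make_mini_alignment_figure(aln: Alignment, spec: RenderSpec) -> plt.Figure:
    fig = plt.figure(figsize=(spec.width, spec.height))
    _mini_axes(fig, build_rgb(aln, spec.palette_for(aln)))
    return fig


def render_mini_alignment(
    aln: Alignment, spec: RenderSpec, path: str | os.PathLike
) -> None:
    """Write a mini-alignment image: one coloured cell per residue."""
    if aln.n_rows == 0 or aln.n_cols == 0:
        raise ValueError("cannot render an empty alignment")
    _save(make_mini_alignment_figure(aln, spec), path, spec)


def make_markup_figure(
    input_aln: Alignment, markup: MarkupMap, spec: RenderSpec
) -> plt.Figure:
    if markup.codes.shape != (input_aln.n_rows, input_aln.n_cols):
        raise ValueError(
            f"markup dimensions {markup.codes.shape} do not match the input "
            f"alignment ({input_aln.n_rows}, {input_aln.n_cols})"
        )
    rgb = build_rgb(input_aln, spec.palette_for(input_aln))
    present: list[str] = []
    for code, label in enumerate(MARKUP_LABELS):
        if code == 0:
            continue
        mask = markup.codes == code
        if mask.any():
            rgb[mask] = to_rgb(spec.markup_palette[label])
            present.append(label)
    fig = plt.figure(figsize=(spec.width, spec.height))
    ax = _mini_axes(fig, rgb)
    handles = [
        Patch(facecolor=spec.markup_palette[label], label=label) for label in present
    ]
    if handles:
        ax.legend(handles=handles, loc="upper right", fontsize="small")
    return fig


def render_markup(
    input_aln: Alignment, markup: MarkupMap, spec: RenderSpec, path: str | os.PathLike
) -> None:
    """Write the input alignment with removed cells over-painted per function."""
    _save(make_markup_figure(input_aln, markup, spec), path, spec)


_LOGO_FONT = FontProperties(family="DejaVu Sans", weight="bold")


def _letter_patch(char: str, x: float, y: float, height: float, colour: str) -> PathPatch:
    path = TextPath((0, 0), char, size=1.0, prop=_LOGO_FONT)
    bbox = path.get_extents()
    if bbox.width == 0 or bbox.height == 0 or height <= 0:
        return PathPatch(path, visible=False)
    stretch = (
        Affine2D()
        .translate(-bbox.x0, -bbox.y0)
        .scale(0.9 / bbox.width, height / bbox.height)
        .translate(x + 0.05, y)
    )
    return PathPatch(stretch.transform_path(path), facecolor=colour, edgecolor="none")


def make_logo_figure(
    cols: Sequence[LogoColumn],
    style: Literal["letters", "bars"],
    spec: RenderSpec,
    alphabet: str = "nucleotide",
    start: int = 0,
) -> plt.Figure:
    if not cols:
        raise ValueError("cannot render a logo from an empty column list")
    if len(cols) > spec.max_logo_columns:
        raise ValueError(
            f"logo window of {len(cols)} columns exceeds the renderer limit "
            f"of {spec.max_logo_columns}; choose a narrower window"
        )
    palette = spec.palette or (
        NUCLEOTIDE_PALETTE if alphabet == "nucleotide" else AMINO_ACID_PALETTE
    )
    max_bits = 2.0 if alphabet == "nucleotide" else float(np.log2(20))
    fig = plt.figure(figsize=(spec.width, spec.height))
    ax = fig.add_subplot(111)
    for i, col in enumerate(cols):
        y = 0.0
        # small letters at the bottom, the most frequent residue on top
        for res, h in sorted(col.heights.items(), key=lambda kv: (kv[1], kv[0])):
            colour = palette.get(res, "#7f7f7f")
            if style == "letters":
                ax.add_patch(_letter_patch(res, i, y, h, colour))
            else:
                ax.add_patch(
                    Rectangle((i + 0.05, y), 0.9, h, facecolor=colour, edgecolor="none")
                )
            y += h
    ax.set_xlim(0, len(cols))
    ax.set_ylim(0, max_bits)
    step = max(1, len(cols) // 10)
    ticks = np.arange(0, len(cols), step)
    ax.set_xticks(ticks + 0.5)
    ax.set_xticklabels([str(start + int(t)) for t in ticks])
    ax.set_xlabel("alignment column")
    ax.set_ylabel("information (bits)")
    return fig


def render_logo(
    cols: Sequence[LogoColumn],
    style: Literal["letters", "bars"],
    spec: RenderSpec,
    path: str | os.PathLike,
    alphabet: str = "nucleotide",
    start: int = 0,
) -> None:
    """Write a sequence logo in letter or rectangle style."""
    _save(make_logo_figure(cols, style, spec, alphabet, start), path, spec)


def make_coverage_figure(profile: CoverageProfile, spec: RenderSpec) -> plt.Figure:
    values = np.asarray(profile.values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot plot an empty coverage profile")
    fig = plt.figure(figsize=(spec.width, spec.height))
    ax = fig.add_subplot(111)
    x = np.arange(values.size)
    ax.fill_between(x, values, step="mid", alpha=0.3, color="#1f77b4")
    ax.plot(x, values, drawstyle="steps-mid", color="#1f77b4")
    ax.set_ylim(0, 1.05)
    ax.set_xlabel("alignment column")
    ax.set_ylabel("coverage")
    return fig


def plot_coverage(
    profile: CoverageProfile, spec: RenderSpec, path: str | os.PathLike
) -> None:
    """Write the per-column coverage plot."""
    _save(make_coverage_figure(profile, spec), path, spec)
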