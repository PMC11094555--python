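"""Deterministic multi-track SVG rendering of gene neighborhoods.

Each neighborhood is one horizontal track of directional gene arrows drawn to
scale (``px_per_kb``); tracks are optionally translated so every anchor
midpoint sits on a common vertical line, and labeled with a chosen taxonomy
rank.  Genes are colored by annotation frequency: a label receives a palette
color only when it occurs at least ``highlight_min_count`` times across the
set (default 3, i.e. "more than twice"); everything else renders gray.

Output is plain SVG 1.1 text with no timestamps and no randomness, so
identical inputs produce byte-identical documents.  Every gene polygon
carries ``class="gene"`` (plus ``anchor`` for anchors) and machine-readable
``data-gene-id`` / ``data-neighborhood-id`` / ``data-labels`` attributes, so
figures remain scriptable after export and glyphs are countable by XML
parsing.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from xml.sax.saxutils import escape, quoteattr

from .align import ClusterOrdering
from .errors import TrackLimitError
from .model import NeighborhoodSet

logger = logging.getLogger(__name__)

#: Fixed qualitative 20-color palette (tab20 hex values); recycled with a
#: logged warning when a set needs more highlighted labels than colors.
PALETTE: tuple[str, ...] = (
    "#1f77b4", "#aec7e8", "#ff7f0e", "#ffbb78", "#2ca02c",
    "#98df8a", "#d62728", "#ff9896", "#9467bd", "#c5b0d5",
    "#8c564b", "#c49c94", "#e377c2", "#f7b6d2", "#7f7f7f",
    "#c7c7c7", "#bcbd22", "#dbdb8d", "#17becf", "#9edae5",
)


@dataclass(frozen=True)
class RenderOptions:
    """Layout and coloring options for :func:`render_svg`."""

    px_per_kb: float = 40.0
    track_height: int = 22
    highlight_min_count: int = 3
    default_color: str = "#c8c8c8"
    palette: tuple[str, ...] = PALETTE
    show_taxonomy: bool = True
    taxonomy_rank: str = "species"
    center_on_anchor: bool = True
    max_tracks: int = 500

    def __post_init__(self) -> None:
        if self.px_per_kb <= 0:
            raise ValueError("px_per_kb must be positive")
        if not self.palette:
            raise ValueError("palette must be non-empty")
        if self.highlight_min_count < 1:
            raise ValueError("highlight_min_count must be >= 1")


@dataclass
class ColorMap:
    """Label -> color assignments plus the occurrence counts behind them."""

    assignments: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def color_for(self, labels: frozenset[str], default: str) -> str:
        # a multi-label gene takes the color of its highest-priority label
        for lab in self.assignments:
            if lab in labels:
                return self.assignments[lab]
        return default


def assign_colors(s: NeighborhoodSet, opts: RenderOptions = RenderOptions()) -> ColorMap:
    """Count labels in the active namespace and color the frequent ones.

    A gene contributes one count per distinct label it carries.  Labels with
    count >= ``highlight_min_count`` take palette colors in descending-count
    order (ties broken alphabetically); the palette recycles with a warning
    if exhausted.
    """
    ns = s.active_namespace
    counts: Counter[str] = Counter()
    for n in s.neighborhoods:
        for g in n.genes:
            counts.update(g.labels_in(ns))
    eligible = sorted(
        (lab for lab, c in counts.items() if c >= opts.highlight_min_count),
        key=lambda lab: (-counts[lab], lab),
    )
    if len(eligible) > len(opts.palette):
        logger.warning(
            "palette exhausted: %d labels to highlight, %d colors; recycling",
            len(eligible), len(opts.palette),
        )
    assignments = {
        lab: opts.palette[i % len(opts.palette)] for i, lab in enumerate(eligible)
    }
    return ColorMap(assignments=assignments, counts=dict(counts))


_TRACK_GAP = 8
_LEGEND_ROW = 18
_MARGIN = 10.0


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def _arrow_points(x1: float, x2: float, y0: float, y1: float, strand: str) -> str:
    ym = (y0 + y1) / 2.0
    head = min(7.0, x2 - x1)
    if strand == "+":
        pts = [(x1, y0), (x2 - head, y0), (x2, ym), (x2 - head, y1), (x1, y1)]
    else:
        pts = [(x2, y0), (x1 + head, y0), (x1, ym), (x1 + head, y1), (x2, y1)]
    return " ".join(f"{_fmt(px)},{_fmt(py)}" for px, py in pts)


def render_svg(
    s: NeighborhoodSet,
    ordering: ClusterOrdering | None = None,
    opts: RenderOptions = RenderOptions(),
) -> str:
    """Render a NeighborhoodSet as a standalone SVG document string.

    Tracks appear in ``ordering.order`` when given, else input order.  Raises
    :class:`TrackLimitError` above ``opts.max_tracks``; an empty set yields a
    valid SVG containing only the (empty) legend block.
    """
    n_tracks = len(s.neighborhoods)
    if n_tracks > opts.max_tracks:
        raise TrackLimitError(f"track limit exceeded ({opts.max_tracks})")
    order = list(ordering.order) if ordering is not None else list(range(n_tracks))
    if sorted(order) != list(range(n_tracks)):
        raise ValueError("ordering is not a permutation of the neighborhood set")
    tracks = [s.neighborhoods[i] for i in order]

    cmap = assign_colors(s, opts)
    scale = opts.px_per_kb / 1000.0  # px per bp
    label_w = 150.0 if opts.show_taxonomy and n_tracks else 0.0

    # per-track x offset; with centering, align all anchor midpoints
    mids = [(t.anchor.midpoint - t.window_start) * scale for t in tracks]
    common = max(mids, default=0.0)
    offsets = []
    for t, mid in zip(tracks, mids):
        off = (common - mid) if opts.center_on_anchor else 0.0
        offsets.append(_MARGIN + label_w + off)
    width = max(
        (
            off + (t.window_end - t.window_start + 1) * scale
            for t, off in zip(tracks, offsets)
        ),
        default=_MARGIN + label_w + 200.0,
    ) + _MARGIN
    row_h = opts.track_height + _TRACK_GAP
    legend_top = _MARGIN + n_tracks * row_h + _MARGIN
    height = legend_top + max(1, len(cmap.assignments)) * _LEGEND_ROW + _MARGIN

    out: list[str] = []
    out.append('<?xml version="1.0" encoding="UTF-8"?>')
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">'
    )
    out.append(
        "<style>.gene{stroke:#333333;stroke-width:0.8;}"
        ".gene.anchor{stroke:#000000;stroke-width:1.6;}"
        ".taxlabel,.legend text{font-family:sans-serif;font-size:11px;}"
        ".backbone{stroke:#999999;stroke-width:1;}</style>"
    )

    for row, (t, off) in enumerate(zip(tracks, offsets)):
        y_top = _MARGIN + row * row_h
        y0 = y_top + opts.track_height * 0.2
        y1 = y_top + opts.track_height * 0.8
        ymid = (y0 + y1) / 2.0
        out.append(f"<g class=\"track\" data-neighborhood-id={quoteattr(t.neighborhood_id)}>")
        if opts.show_taxonomy:
            name = t.source.taxon_name(opts.taxonomy_rank) or t.source.genome_id
            out.append(
                f'<text class="taxlabel" x="{_fmt(4.0)}" y="{_fmt(ymid + 4)}">'
                f"{escape(name)}</text>"
            )
        x_left = off
        x_right = off + (t.window_end - t.window_start + 1) * scale
        out.append(
            f'<line class="backbone" x1="{_fmt(x_left)}" y1="{_fmt(ymid)}" '
            f'x2="{_fmt(x_right)}" y2="{_fmt(ymid)}"/>'
        )
        for g in t.genes:
            x1 = off + (g.start - t.window_start) * scale
            x2 = off + (g.end - t.window_start + 1) * scale
            labels = sorted(g.labels_in(s.active_namespace))
            fill = cmap.color_for(frozenset(labels), opts.default_color)
            cls = "gene anchor" if g.gene_id == t.anchor_id else "gene"
            out.append(
                f'<polygon class="{cls}" points="{_arrow_points(x1, x2, y0, y1, g.strand)}" '
                f'fill="{fill}" '
                f"data-gene-id={quoteattr(g.gene_id)} "
                f"data-neighborhood-id={quoteattr(t.neighborhood_id)} "
                f"data-labels={quoteattr(','.join(labels))}>"
                f"<title>{escape(g.product or g.gene_id)}</title></polygon>"
            )
        out.append("</g>")

    out.append('<g class="legend">')
    for i, (lab, color) in enumerate(cmap.assignments.items()):
        y = legend_top + i * _LEGEND_ROW
        out.append(
            f'<rect x="{_fmt(_MARGIN)}" y="{_fmt(y)}" width="12" height="12" '
            f'fill="{color}" stroke="#333333"/>'
        )
        out.append(
            f'<text x="{_fmt(_MARGIN + 18)}" y="{_fmt(y + 10)}">'
            f"{escape(lab)} (n={cmap.counts[lab]})</text>"
        )
    out.append("</g>")
    out.append("</svg>")
    return "\n".join(out) + "\n"
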