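"""Deterministic static SVG rendering of a cluster-heatmap document.

Layout follows the classic composition: column dendrogram on top, row
dendrogram on the left, the heatmap in the centre and metadata columns on the
right, each metadata column on its own colour scale (categorical columns use
a fixed qualitative palette).  Rendering is a pure function of (document,
options): the same input always produces byte-identical SVG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .document import DocumentError, HeatmapDocument, validate
from .explore import leaf_order
from .hcluster import DendrogramTree

__all__ = ["RenderOptions", "COLOUR_SCALES", "CATEGORICAL_PALETTE", "value_to_colour", "render"]

# 3-stop linear scales (low -> mid -> high), hex RGB
COLOUR_SCALES: dict[str, tuple[str, str, str]] = {
    "Greens": ("#f7fcf5", "#74c476", "#00441b"),
    "Reds": ("#fff5f0", "#fb6a4a", "#67000d"),
    "Blues": ("#f7fbff", "#6baed6", "#08306b"),
    "Greys": ("#ffffff", "#969696", "#000000"),
    "YlGnBu": ("#ffffd9", "#41b6c4", "#081d58"),
    "YlOrRd": ("#ffffcc", "#fd8d3c", "#800026"),
    "BuWhRd": ("#2166ac", "#f7f7f7", "#b2182b"),
}

CATEGORICAL_PALETTE = (
    "#1b9e77", "#d95f02", "#7570b3", "#e7298a", "#66a61e",
    "#e6ab02", "#a6761d", "#666666", "#8dd3c7", "#bebada",
)


@dataclass
class RenderOptions:
    data_scale: str = "YlGnBu"
    metadata_scale: str = "Greens"
    heatmap_visible: bool = True
    highlight: list[str] = field(default_factory=list)  # leaf IDs
    highlight_scale: str = "Reds"
    per_column_range: bool = False
    cell_size: float = 14.0
    font_size: float = 10.0
    dendrogram_size: float = 90.0  # pixels reserved for each dendrogram

    def __post_init__(self) -> None:
        for name in (self.data_scale, self.metadata_scale, self.highlight_scale):
            if name not in COLOUR_SCALES:
                raise KeyError(f"unknown colour scale {name!r}")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")


def _hex_to_rgb(h: str) -> tuple[int, int, int]:
    return int(h[1:3], 16), int(h[3:5], 16), int(h[5:7], 16)


def value_to_colour(value: float, lo: float, hi: float, scale: str = "YlGnBu") -> str:
    """Linear interpolation across the scale's stops; values are clamped to
    [lo, hi] and a degenerate range (lo == hi) maps to the scale midpoint."""
    stops = COLOUR_SCALES.get(scale)
    if stops is None:
        raise KeyError(f"unknown colour scale {scale!r}")
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    t = 0.5 if lo == hi else min(1.0, max(0.0, (value - lo) / (hi - lo)))
    pos = t * (len(stops) - 1)
    i = min(int(pos), len(stops) - 2)
    frac = pos - i
    a, b = _hex_to_rgb(stops[i]), _hex_to_rgb(stops[i + 1])
    rgb = tuple(round(a[c] + frac * (b[c] - a[c])) for c in range(3))
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def _f(v: float) -> str:
    return f"{v:.2f}"


def _dendrogram_segments(
    tree: DendrogramTree, positions: dict[str, float], extent: float
) -> tuple[dict[str, tuple[float, float]], list[tuple[float, float, float, float]]]:
    """Per-node (offset, along) coordinates plus elbow line segments.

    ``offset`` runs from 0 at the deepest merge to ``extent`` at the leaves,
    so branch positions are monotone in node distance; ``along`` is the
    position across the leaf axis.
    """
    max_d = max((nd.distance for nd in tree.nodes.values()), default=0.0) or 1.0
    coords: dict[str, tuple[float, float]] = {}
    segments: list[tuple[float, float, float, float]] = []

    def along(nid: str) -> float:
        nd = tree.nodes[nid]
        if nd.is_leaf:
            return positions[nid]
        return 0.5 * (along_cache[nd.left] + along_cache[nd.right])

    along_cache: dict[str, float] = {}
    # children before parents: leaves first, then inner nodes by subtree size
    for nid in sorted(tree.nodes, key=lambda i: tree.nodes[i].count):
        along_cache[nid] = along(nid)
        offset = extent * (1.0 - tree.nodes[nid].distance / max_d)
        coords[nid] = (offset, along_cache[nid])
    for nid, nd in tree.nodes.items():
        if nd.is_leaf:
            continue
        off, _ = coords[nid]
        for child in (nd.left, nd.right):
            c_off, c_along = coords[child]
            segments.append((off, coords[nid][1], off, c_along))   # cross bar half
            segments.append((off, c_along, c_off, c_along))        # drop to child
    return coords, segments


def render(doc: HeatmapDocument, opts: RenderOptions | None = None) -> str:
    """Render the document to SVG text (byte-identical for identical inputs)."""
    opts = opts or RenderOptions()
    problems = validate(doc)
    if problems:
        raise DocumentError("refusing to render an invalid document:\n" + "\n".join(problems))

    rows = leaf_order(doc.row_tree)
    n = len(rows)
    m = len(doc.feature_names)
    cs = opts.cell_size
    pad = 4.0
    row_dw = opts.dendrogram_size
    col_dh = opts.dendrogram_size if doc.column_tree is not None else 0.0
    heat_w = m * cs if opts.heatmap_visible else 0.0
    meta_names = doc.metadata_feature_names or []
    meta_w = len(meta_names) * cs if doc.metadata_nodes is not None else 0.0
    label_w = 80.0
    x_heat = row_dw + pad
    x_meta = x_heat + heat_w + (pad if heat_w else 0.0)
    x_label = x_meta + meta_w + pad
    y_heat = col_dh + pad
    width = x_label + label_w
    height = y_heat + n * cs + pad

    out: list[str] = []
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_f(width)}" height="{_f(height)}">'
    )
    out.append(f'<rect x="0" y="0" width="{_f(width)}" height="{_f(height)}" fill="#ffffff"/>')

    # row dendrogram (left; root farthest from the leaves)
    row_pos = {nid: y_heat + (i + 0.5) * cs for i, nid in enumerate(rows)}
    _, segs = _dendrogram_segments(doc.row_tree, row_pos, row_dw)
    out.append('<g class="row-dendrogram" stroke="#333333" stroke-width="1" fill="none">')
    for off, a, off2, a2 in segs:
        out.append(f'<line x1="{_f(off)}" y1="{_f(a)}" x2="{_f(off2)}" y2="{_f(a2)}"/>')
    out.append("</g>")

    # column dendrogram (top)
    if doc.column_tree is not None:
        col_leaves = leaf_order(doc.column_tree)
        col_pos = {nid: x_heat + (i + 0.5) * cs for i, nid in enumerate(col_leaves)}
        _, segs = _dendrogram_segments(doc.column_tree, col_pos, col_dh)
        out.append('<g class="column-dendrogram" stroke="#333333" stroke-width="1" fill="none">')
        for off, a, off2, a2 in segs:
            out.append(f'<line x1="{_f(a)}" y1="{_f(off)}" x2="{_f(a2)}" y2="{_f(off2)}"/>')
        out.append("</g>")

    # heatmap cells
    if opts.heatmap_visible:
        values = [doc.row_tree.nodes[nid].features or [] for nid in rows]
        if opts.per_column_range:
            ranges = [
                (min(r[j] for r in values), max(r[j] for r in values)) for j in range(m)
            ]
        else:
            flat = [v for r in values for v in r]
            ranges = [(min(flat), max(flat))] * m
        out.append('<g class="heatmap">')
        for i, nid in enumerate(rows):
            for j in range(m):
                lo, hi = ranges[j]
                colour = value_to_colour(values[i][j], lo, hi, opts.data_scale)
                out.append(
                    f'<rect class="data-cell" x="{_f(x_heat + j * cs)}" '
                    f'y="{_f(y_heat + i * cs)}" width="{_f(cs)}" height="{_f(cs)}" '
                    f'fill="{colour}"/>'
                )
        out.append("</g>")

    # metadata columns, each on its own scale
    if doc.metadata_nodes is not None:
        k = len(meta_names)
        numeric_ranges: list[tuple[float, float] | None] = []
        cat_maps: list[dict[str, str]] = []
        for j in range(k):
            cells = [doc.metadata_nodes[nid][j] for nid in rows if nid in doc.metadata_nodes]
            nums = [c for c in cells if isinstance(c, (int, float)) and not isinstance(c, bool)]
            if cells and len(nums) == len(cells):
                numeric_ranges.append((min(nums), max(nums)))
                cat_maps.append({})
            else:
                labels = sorted({str(c) for c in cells if c is not None})
                numeric_ranges.append(None)
                cat_maps.append(
                    {lab: CATEGORICAL_PALETTE[i % len(CATEGORICAL_PALETTE)]
                     for i, lab in enumerate(labels)}
                )
        out.append('<g class="metadata">')
        for i, nid in enumerate(rows):
            vals = doc.metadata_nodes.get(nid)
            if vals is None:
                continue
            for j in range(k):
                v = vals[j]
                if v is None:
                    continue
                if numeric_ranges[j] is not None:
                    lo, hi = numeric_ranges[j]
                    colour = value_to_colour(float(v), lo, hi, opts.metadata_scale)
                else:
                    colour = cat_maps[j][str(v)]
                out.append(
                    f'<rect class="meta-cell" x="{_f(x_meta + j * cs)}" '
                    f'y="{_f(y_heat + i * cs)}" width="{_f(cs)}" height="{_f(cs)}" '
                    f'fill="{colour}"/>'
                )
        out.append("</g>")

    # highlight overlay across the full row
    if opts.highlight:
        colour = COLOUR_SCALES[opts.highlight_scale][1]
        out.append('<g class="highlight">')
        for i, nid in enumerate(rows):
            if nid in opts.highlight:
                out.append(
                    f'<rect class="highlight-row" x="{_f(x_heat)}" y="{_f(y_heat + i * cs)}" '
                    f'width="{_f(max(heat_w + meta_w + pad, cs))}" height="{_f(cs)}" '
                    f'fill="{colour}" fill-opacity="0.45"/>'
                )
        out.append("</g>")

    # row labels: the data-point IDs carried by each leaf
    out.append(f'<g class="labels" font-family="sans-serif" font-size="{_f(opts.font_size)}">')
    for i, nid in enumerate(rows):
        objs = doc.row_tree.nodes[nid].objects or []
        label = objs[0] + (f" (+{len(objs) - 1})" if len(objs) > 1 else "")
        out.append(
            f'<text x="{_f(x_label)}" y="{_f(y_heat + (i + 0.7) * cs)}">{_escape(label)}</text>'
        )
    out.append("</g>")
    out.append("</svg>")
    return "\n".join(out) + "\n"


def _escape(text: str) -> str:
    return text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
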