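"""Render a document to a static SVG cluster heatmap.

Row dendrogram on the left, heatmap in the centre, metadata on the right in
its own colour scale, column dendrogram on top; two highlighted rows get a
red overlay.  The output is deterministic: same document + options, same
bytes.
"""

from pathlib import Path

from dendroheat import BlobSpec, RenderOptions, leaf_order, make_document, render

doc = make_document(BlobSpec(n_rows=15, n_features=5, n_clusters=3, seed=9))
opts = RenderOptions(
    data_scale="YlGnBu",
    metadata_scale="Greens",
    highlight=leaf_order(doc.row_tree)[:2],  # first two displayed rows
    highlight_scale="Reds",
)
svg = render(doc, opts)

out = Path("scratch")
out.mkdir(exist_ok=True)
path = out / "heatmap.svg"
path.write_text(svg)
print(f"wrote {path} ({len(svg)} bytes)")
print(f"data cells: {svg.count('data-cell')}, metadata cells: {svg.count('meta-cell')}, "
      f"highlighted rows: {svg.count('highlight-row')}")
# 15 rows x 5 features = 75 data cells, 30 metadata cells (2 columns), and
# the 2 requested highlight overlays; open the file in any browser.
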