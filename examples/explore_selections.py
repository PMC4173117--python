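"""Programmatic exploration: select clusters, look up rows, zoom to k groups.

These calls mirror what an interactive viewer does on clicks — select a
dendrogram node to harvest its compound IDs, or map IDs back to the heatmap
rows to highlight.
"""

from dendroheat import (
    BlobSpec,
    cut_at,
    leaf_order,
    make_document,
    objects_under,
    rows_for_objects,
)

doc = make_document(BlobSpec(n_rows=12, n_features=4, n_clusters=3, seed=5))
tree = doc.row_tree

print("display order:", leaf_order(tree))

root_sel = objects_under(tree, tree.root_id)
print(f"root selection: {len(root_sel.object_ids)} objects")

three = cut_at(tree, 3)
print("zoom to 3 clusters:", three)
for node in three:
    sel = objects_under(tree, node)
    print(f"  {node}: {sel.object_ids}")

hits, unknown = rows_for_objects(doc, ["r0", "r5", "martian"])
print("rows highlighting r0/r5:", hits, "| unknown IDs:", unknown)
# cut_at partitions the rows into the 3 top-level clusters (the blobs the
# generator planted); rows_for_objects returns the leaf rows to highlight
# and reports IDs that exist nowhere in the heatmap.
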