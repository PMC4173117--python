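"""Programmatic exploration of a dendrogram: selection, highlighting, cutting.

These are the batch equivalents of clicking around an interactive heatmap:
select a dendrogram node and get the data-point IDs beneath it, find the
heatmap rows carrying given IDs (scaffold-highlight semantics), or zoom the
tree out to its k top-level clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

from .document import HeatmapDocument
from .hcluster import DendrogramTree

__all__ = ["Selection", "leaf_order", "objects_under", "rows_for_objects", "cut_at"]


@dataclass
class Selection:
    """A selected dendrogram node with its leaves and data-point IDs in display order."""

    node_id: str
    leaf_ids: list[str]
    object_ids: list[str]


def leaf_order(tree: DendrogramTree) -> list[str]:
    """Leaves in display order: depth-first, left child before right."""
    order: list[str] = []
    stack = [tree.root_id]
    while stack:
        nid = stack.pop()
        nd = tree.nodes[nid]
        if nd.is_leaf:
            order.append(nid)
        else:
            stack.append(nd.right)  # right pushed first so left pops first
            stack.append(nd.left)
    return order


def _subtree_leaves(tree: DendrogramTree, node_id: str) -> list[str]:
    order: list[str] = []
    stack = [node_id]
    while stack:
        nid = stack.pop()
        nd = tree.nodes[nid]
        if nd.is_leaf:
            order.append(nid)
        else:
            stack.append(nd.right)
            stack.append(nd.left)
    return order


def objects_under(tree: DendrogramTree, node_id: str) -> Selection:
    """All leaves and (concatenated, order-preserving) object IDs under a node."""
    if node_id not in tree.nodes:
        raise KeyError(f"unknown node ID {node_id!r}")
    leaves = _subtree_leaves(tree, node_id)
    objects = [obj for nid in leaves for obj in (tree.nodes[nid].objects or [])]
    return Selection(node_id, leaves, objects)


def rows_for_objects(
    doc: HeatmapDocument, object_ids: list[str]
) -> tuple[list[str], list[str]]:
    """Leaves whose objects intersect the query, in display order, plus unknown IDs."""
    query = set(object_ids)
    hits = []
    known: set[str] = set()
    for nid in leaf_order(doc.row_tree):
        objs = doc.row_tree.nodes[nid].objects or []
        known.update(objs)
        if query.intersection(objs):
            hits.append(nid)
    unknown = [obj for obj in object_ids if obj not in known]
    return hits, unknown


def cut_at(tree: DendrogramTree, k: int) -> list[str]:
    """The k subtree roots obtained by removing the k-1 highest merges.

    Ties in height are resolved by merge order (later merges are removed
    first), so the cut is deterministic; the selected nodes always partition
    the leaves.  Returned in display order.
    """
    n = tree.nodes[tree.root_id].count
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")

    def rank(nid: str) -> tuple[float, tuple]:
        head, _, tail = nid.rpartition("_")
        order = (head, int(tail)) if tail.isdigit() else (nid, -1)
        return (tree.nodes[nid].distance, order)

    selection = [tree.root_id]
    for _ in range(k - 1):
        inner = [nid for nid in selection if not tree.nodes[nid].is_leaf]
        split = max(inner, key=rank)
        nd = tree.nodes[split]
        selection.remove(split)
        selection.extend([nd.left, nd.right])
    position = {nid: i for i, nid in enumerate(leaf_order(tree))}
    return sorted(selection, key=lambda nid: position[_subtree_leaves(tree, nid)[0]])
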