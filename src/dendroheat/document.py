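"""The three-block cluster-heatmap JSON document: build, serialize, parse, validate.

A document has a mandatory ``data`` block (feature names plus the row
dendrogram, whose leaves carry ``features`` and ``objects``), an optional
``metadata`` block (its own feature names plus a leaf-ID-keyed map of value
lists), and an optional ``column_dendrogram`` block (a dendrogram over the
feature axis whose leaves carry neither features nor objects).

Conventions:

* node keys are exactly ``count``, ``distance``, ``features``, ``objects``,
  ``parent``, ``left_child``, ``right_child``; the root is the only node
  emitted without a ``parent`` key;
* a leaf's ``count`` is always 1 even when its ``objects`` list holds several
  compressed data points — count counts heatmap rows, not data points;
* when a column dendrogram is present the feature order is materialized:
  ``feature_names`` and every leaf's ``features`` are permuted into the
  column tree's leaf order;
* unknown keys in parsed input are preserved opaquely and re-emitted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

from .hcluster import DendrogramTree, TreeNode
from .reduce_rows import RowGrouping, aggregate_metadata
from .tabular_io import MetadataTable

__all__ = ["HeatmapDocument", "DocumentError", "build_document", "serialize", "parse", "validate"]

_LEAF_KEYS = ("count", "distance", "features", "objects", "parent")
_INNER_KEYS = ("count", "distance", "parent", "left_child", "right_child")


class DocumentError(ValueError):
    """Raised when a document cannot be parsed or fails validation."""


@dataclass
class HeatmapDocument:
    """In-memory form of the three-block document."""

    feature_names: list[str]
    row_tree: DendrogramTree
    metadata_feature_names: list[str] | None = None
    metadata_nodes: dict[str, list[object]] | None = None
    column_tree: DendrogramTree | None = None
    extra: dict = field(default_factory=dict)

    def leaf_ids(self) -> list[str]:
        from .explore import leaf_order

        return leaf_order(self.row_tree)


def _leaf_order_indices(tree: DendrogramTree) -> list[int]:
    """Display order of a built column tree as original column indices."""
    from .explore import leaf_order

    return [int(nid.rsplit("_", 1)[1]) for nid in leaf_order(tree)]


def build_document(
    row_tree: DendrogramTree,
    col_tree: DendrogramTree | None = None,
    metadata: MetadataTable | None = None,
    feature_names: list[str] | None = None,
    meta_stat: str = "mean",
) -> HeatmapDocument:
    """Assemble the document from its parts.

    Metadata rows are keyed by object ID and mapped onto leaves through each
    leaf's ``objects`` list; a leaf holding several compressed data points
    gets its metadata aggregated (numeric by *meta_stat*, categorical by
    majority).  Metadata IDs matching no leaf are dropped with a warning.
    """
    if feature_names is None:
        raise ValueError("feature_names are required")
    feature_names = list(feature_names)
    nodes = {nid: _copy_node(nd) for nid, nd in row_tree.nodes.items()}
    row_tree = DendrogramTree(nodes, row_tree.root_id)

    if col_tree is not None:
        if col_tree.n_leaves() != len(feature_names):
            raise DocumentError(
                f"column dendrogram has {col_tree.n_leaves()} leaves "
                f"for {len(feature_names)} features"
            )
        perm = _leaf_order_indices(col_tree)
        feature_names = [feature_names[j] for j in perm]
        for nd in row_tree.nodes.values():
            if nd.is_leaf and nd.features is not None:
                nd.features = [nd.features[j] for j in perm]

    meta_names = None
    meta_nodes = None
    if metadata is not None:
        meta_names = list(metadata.feature_names)
        index = {rid: i for i, rid in enumerate(metadata.row_ids)}
        meta_nodes = {}
        used: set[str] = set()
        for nid, nd in row_tree.nodes.items():
            if not nd.is_leaf:
                continue
            hits = [i for obj in (nd.objects or []) for i in ([index[obj]] if obj in index else [])]
            used.update(obj for obj in (nd.objects or []) if obj in index)
            if not hits:
                continue
            if len(hits) == 1:
                meta_nodes[nid] = list(metadata.values[hits[0]])
            else:
                sub = aggregate_metadata(metadata, RowGrouping([hits]), meta_stat)
                meta_nodes[nid] = list(sub.values[0])
        unmatched = [rid for rid in metadata.row_ids if rid not in used]
        if unmatched:
            warnings.warn(
                f"{len(unmatched)} metadata ID(s) matched no leaf and were dropped",
                stacklevel=2,
            )
    return HeatmapDocument(feature_names, row_tree, meta_names, meta_nodes, col_tree)


def _copy_node(nd: TreeNode) -> TreeNode:
    return TreeNode(
        parent=nd.parent,
        left=nd.left,
        right=nd.right,
        count=nd.count,
        distance=nd.distance,
        features=list(nd.features) if nd.features is not None else None,
        objects=list(nd.objects) if nd.objects is not None else None,
        extra=dict(nd.extra),
    )


def _num(x: object, digits: int | None) -> object:
    """Emit integral floats as ints (``distance: 0``, not ``0.0``)."""
    if isinstance(x, bool) or not isinstance(x, (int, float)):
        return x
    v = float(x)
    if digits is not None:
        v = round(v, digits)
    return int(v) if v.is_integer() else v


def _node_id_key(nid: str):
    head, _, tail = nid.rpartition("_")
    return (head, int(tail)) if tail.isdigit() else (nid, -1)


def _tree_to_json(tree: DendrogramTree, digits: int | None) -> dict:
    out: dict[str, dict] = {}
    for nid in sorted(tree.nodes, key=_node_id_key):
        nd = tree.nodes[nid]
        rec: dict[str, object] = {"count": nd.count, "distance": _num(nd.distance, digits)}
        if nd.is_leaf:
            if nd.features is not None:
                rec["features"] = [_num(v, None) for v in nd.features]
            if nd.objects is not None:
                rec["objects"] = list(nd.objects)
        else:
            rec["left_child"] = nd.left
            rec["right_child"] = nd.right
        if nd.parent is not None:
            rec["parent"] = nd.parent
        rec.update(nd.extra)
        out[nid] = rec
    return out


def serialize(doc: HeatmapDocument, digits: int | None = None) -> str:
    """Serialize a validated document to JSON text.

    Key order is deterministic; numbers are emitted without precision loss
    (*digits*, if given, rounds dendrogram distances for compactness).
    """
    problems = validate(doc)
    if problems:
        raise DocumentError("refusing to serialize an invalid document:\n" + "\n".join(problems))
    body: dict[str, object] = {
        "data": {
            "feature_names": list(doc.feature_names),
            "nodes": _tree_to_json(doc.row_tree, digits),
        }
    }
    if doc.metadata_nodes is not None:
        body["metadata"] = {
            "feature_names": list(doc.metadata_feature_names or []),
            "nodes": {
                nid: [_num(v, None) for v in vals]
                for nid, vals in sorted(doc.metadata_nodes.items(), key=lambda kv: _node_id_key(kv[0]))
            },
        }
    if doc.column_tree is not None:
        body["column_dendrogram"] = {"nodes": _tree_to_json(doc.column_tree, digits)}
    body.update(doc.extra)
    return json.dumps(body, indent=2, ensure_ascii=False) + "\n"


def _parse_tree(nodes_json: dict, block: str) -> DendrogramTree:
    nodes: dict[str, TreeNode] = {}
    for nid, rec in nodes_json.items():
        if not isinstance(rec, dict):
            raise DocumentError(f"{block} node {nid!r} is not an object")
        for key in ("count", "distance"):
            if key not in rec:
                raise DocumentError(f"{block} node {nid!r} is missing the {key!r} key")
        is_inner = "left_child" in rec or "right_child" in rec
        if is_inner and ("left_child" not in rec or "right_child" not in rec):
            raise DocumentError(f"{block} node {nid!r} has only one child key")
        known = set(_INNER_KEYS if is_inner else _LEAF_KEYS)
        extra = {k: v for k, v in rec.items() if k not in known}
        nodes[nid] = TreeNode(
            parent=rec.get("parent"),
            left=rec.get("left_child"),
            right=rec.get("right_child"),
            count=int(rec["count"]),
            distance=float(rec["distance"]),
            features=[float(v) for v in rec["features"]] if "features" in rec else None,
            objects=[str(o) for o in rec["objects"]] if "objects" in rec else None,
            extra=extra,
        )
    roots = [nid for nid, nd in nodes.items() if nd.parent is None]
    if len(roots) != 1:
        raise DocumentError(f"{block} block has {len(roots)} parentless nodes; expected exactly 1")
    return DendrogramTree(nodes, roots[0])


def parse(text: str) -> HeatmapDocument:
    """Parse JSON text into a :class:`HeatmapDocument`.

    Unknown keys (at the top level and inside nodes) are preserved opaquely
    so that round-tripping a document from a newer producer loses nothing.
    """
    try:
        body = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DocumentError(f"malformed JSON: {exc}") from exc
    if not isinstance(body, dict) or "data" not in body:
        raise DocumentError("data block missing")
    data = body["data"]
    if "nodes" not in data:
        raise DocumentError("data block is missing the 'nodes' key")
    if "feature_names" not in data:
        raise DocumentError("data block is missing the 'feature_names' key")
    row_tree = _parse_tree(data["nodes"], "data")

    meta_names = meta_nodes = None
    if "metadata" in body:
        meta = body["metadata"]
        if "nodes" not in meta or "feature_names" not in meta:
            raise DocumentError("metadata block needs 'feature_names' and 'nodes'")
        meta_names = [str(f) for f in meta["feature_names"]]
        meta_nodes = {str(k): list(v) for k, v in meta["nodes"].items()}

    col_tree = None
    if "column_dendrogram" in body:
        cd = body["column_dendrogram"]
        if "nodes" not in cd:
            raise DocumentError("column_dendrogram block is missing the 'nodes' key")
        col_tree = _parse_tree(cd["nodes"], "column_dendrogram")

    extra = {k: v for k, v in body.items() if k not in ("data", "metadata", "column_dendrogram")}
    return HeatmapDocument(
        [str(f) for f in data["feature_names"]], row_tree, meta_names, meta_nodes, col_tree, extra
    )


def _validate_tree(tree: DendrogramTree, block: str, out: list[str]) -> None:
    roots = [nid for nid, nd in tree.nodes.items() if nd.parent is None]
    if len(roots) != 1:
        out.append(f"{block}: {len(roots)} parentless nodes (multiple roots)" if len(roots) > 1
                   else f"{block}: no root node")
    elif roots[0] != tree.root_id:
        out.append(f"{block}: recorded root {tree.root_id!r} is not the parentless node")
    for nid, nd in tree.nodes.items():
        if (nd.left is None) != (nd.right is None):
            out.append(f"{block} node {nid}: has exactly one child")
            continue
        if nd.is_leaf:
            if nd.count != 1:
                out.append(f"{block} node {nid}: leaf count must be 1, found {nd.count}")
            if nd.distance != 0:
                out.append(f"{block} node {nid}: leaf distance must be 0, found {nd.distance}")
        else:
            for child in (nd.left, nd.right):
                if child not in tree.nodes:
                    out.append(f"{block} node {nid}: child {child!r} does not exist")
                elif tree.nodes[child].parent != nid:
                    out.append(f"{block} node {nid}: child {child!r} does not point back to it")
            if nd.left in tree.nodes and nd.right in tree.nodes:
                expect = tree.nodes[nd.left].count + tree.nodes[nd.right].count
                if nd.count != expect:
                    out.append(
                        f"{block} node {nid}: count {nd.count} != sum of children counts {expect}"
                    )
        if nd.distance < 0:
            out.append(f"{block} node {nid}: negative distance")
        if nd.parent is not None and nd.parent not in tree.nodes:
            out.append(f"{block} node {nid}: parent {nd.parent!r} does not exist")


def validate(doc: HeatmapDocument) -> list[str]:
    """Check every document invariant; returns violations (empty list = valid)."""
    out: list[str] = []
    _validate_tree(doc.row_tree, "data", out)
    m = len(doc.feature_names)
    seen_objects: dict[str, str] = {}
    for nid, nd in doc.row_tree.nodes.items():
        if not nd.is_leaf:
            continue
        if nd.features is None:
            out.append(f"data node {nid}: leaf has no features")
        elif len(nd.features) != m:
            out.append(f"data node {nid}: {len(nd.features)} features for {m} feature names")
        if not nd.objects:
            out.append(f"data node {nid}: leaf has no objects")
        else:
            for obj in nd.objects:
                if obj in seen_objects:
                    out.append(
                        f"data node {nid}: object {obj!r} already carried by {seen_objects[obj]}"
                    )
                seen_objects[obj] = nid
    if doc.metadata_nodes is not None:
        leaf_ids = {nid for nid, nd in doc.row_tree.nodes.items() if nd.is_leaf}
        k = len(doc.metadata_feature_names or [])
        for nid, vals in doc.metadata_nodes.items():
            if nid not in leaf_ids:
                out.append(f"metadata key {nid!r} is not a leaf of the data tree")
            if len(vals) != k:
                out.append(f"metadata node {nid}: {len(vals)} values for {k} feature names")
    if doc.column_tree is not None:
        _validate_tree(doc.column_tree, "column_dendrogram", out)
        for nid, nd in doc.column_tree.nodes.items():
            if nd.is_leaf and (nd.features is not None or nd.objects is not None):
                out.append(f"column_dendrogram node {nid}: leaves carry no features or objects")
        if doc.column_tree.n_leaves() != m:
            out.append(
                f"column_dendrogram has {doc.column_tree.n_leaves()} leaves "
                f"for {m} feature names"
            )
    return out
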