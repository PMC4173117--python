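import json

import numpy as np
import pytest

from dendroheat import (
    BlobSpec,
    DataMatrix,
    DocumentError,
    MetadataTable,
    build_document,
    build_tree,
    compute_linkage,
    make_document,
    parse,
    serialize,
    validate,
)

# a minimal two-leaf document in the wire format, with the documented
# leaf/node key vocabulary (count/distance/features/objects/parent/children)
TWO_LEAF_JSON = """
{
  "data": {
    "feature_names": ["f1", "f2", "f3"],
    "nodes": {
      "leaf_0": {
        "count": 1,
        "distance": 0,
        "features": [1.4, 3.5, 5.1],
        "parent": "node_0",
        "objects": ["object_1", "object_2"]
      },
      "leaf_1": {
        "count": 1,
        "distance": 0,
        "features": [2.0, 2.0, 2.0],
        "parent": "node_0",
        "objects": ["object_3"]
      },
      "node_0": {
        "count": 2,
        "distance": 3.32,
        "left_child": "leaf_0",
        "right_child": "leaf_1"
      }
    }
  },
  "metadata": {
    "feature_names": ["Numeric", "Categoric"],
    "nodes": {
      "leaf_0": [0.03, "positive"],
      "leaf_1": [0.02, "negative"]
    }
  }
}
"""


class TestParse:
    def test_leaf_fields(self):
        doc = parse(TWO_LEAF_JSON)
        leaf = doc.row_tree.nodes["leaf_0"]
        assert leaf.count == 1
        assert leaf.distance == 0
        assert leaf.features == [1.4, 3.5, 5.1]
        assert leaf.parent == "node_0"
        assert leaf.objects == ["object_1", "object_2"]

    def test_inner_node_fields(self):
        doc = parse(TWO_LEAF_JSON)
        node = doc.row_tree.nodes["node_0"]
        assert node.count == 2
        assert node.distance == pytest.approx(3.32)
        assert (node.left, node.right) == ("leaf_0", "leaf_1")
        assert doc.row_tree.root_id == "node_0"

    def test_metadata_block(self):
        doc = parse(TWO_LEAF_JSON)
        assert doc.metadata_feature_names == ["Numeric", "Categoric"]
        assert doc.metadata_nodes["leaf_0"] == [0.03, "positive"]

    def test_empty_object_is_missing_data_block(self):
        with pytest.raises(DocumentError, match="data block missing"):
            parse("{}")

    def test_missing_mandatory_key_names_node_and_key(self):
        body = json.loads(TWO_LEAF_JSON)
        del body["data"]["nodes"]["leaf_0"]["count"]
        with pytest.raises(DocumentError, match="leaf_0.*'count'"):
            parse(json.dumps(body))

    def test_malformed_json(self):
        with pytest.raises(DocumentError, match="malformed JSON"):
            parse("{not json")

    def test_unknown_keys_preserved_through_roundtrip(self):
        body = json.loads(TWO_LEAF_JSON)
        body["producer"] = {"tool": "elsewhere"}
        body["data"]["nodes"]["leaf_0"]["colour_hint"] = "red"
        doc = parse(json.dumps(body))
        again = json.loads(serialize(doc))
        assert again["producer"] == {"tool": "elsewhere"}
        assert again["data"]["nodes"]["leaf_0"]["colour_hint"] == "red"


class TestSerialize:
    def test_leaf_distance_serialized_as_integer_zero(self):
        text = serialize(parse(TWO_LEAF_JSON))
        assert '"distance": 0,' in text

    def test_root_has_no_parent_key(self):
        body = json.loads(serialize(parse(TWO_LEAF_JSON)))
        assert "parent" not in body["data"]["nodes"]["node_0"]
        assert body["data"]["nodes"]["leaf_0"]["parent"] == "node_0"

    def test_digits_option_rounds_distances(self):
        doc = make_document(BlobSpec(n_rows=6, seed=1))
        body = json.loads(serialize(doc, digits=2))
        for rec in body["data"]["nodes"].values():
            assert round(rec["distance"], 2) == rec["distance"]

    def test_refuses_invalid_document(self):
        doc = parse(TWO_LEAF_JSON)
        doc.row_tree.nodes["node_0"].count = 99
        with pytest.raises(DocumentError, match="refusing"):
            serialize(doc)

    @pytest.mark.parametrize("seed", range(6))
    def test_roundtrip_identity_on_pipeline_documents(self, seed):
        doc = make_document(
            BlobSpec(n_rows=8 + seed, n_features=3, seed=seed),
            compress=None if seed % 2 else 4,
            write_original=bool(seed % 2),
        )
        assert parse(serialize(doc)) == doc


class TestValidate:
    def test_pipeline_documents_are_valid(self, pipeline_document):
        assert validate(pipeline_document) == []

    def test_bad_inner_count_is_one_violation(self):
        doc = parse(TWO_LEAF_JSON)
        doc.row_tree.nodes["node_0"].count = 3
        problems = validate(doc)
        assert len(problems) == 1 and "count" in problems[0]

    def test_multiple_roots_violation(self):
        doc = parse(TWO_LEAF_JSON)
        doc.row_tree.nodes["leaf_1"].parent = None
        assert any("multiple roots" in p for p in validate(doc))

    def test_duplicated_object_across_leaves(self):
        doc = parse(TWO_LEAF_JSON)
        doc.row_tree.nodes["leaf_1"].objects = ["object_1"]
        assert any("already carried" in p for p in validate(doc))

    def test_metadata_key_must_be_a_leaf(self):
        doc = parse(TWO_LEAF_JSON)
        doc.metadata_nodes["ghost"] = [1, "positive"]
        assert any("ghost" in p for p in validate(doc))


class TestBuildDocument:
    def tree_for(self, values, ids):
        data = DataMatrix(ids, [f"f{j}" for j in range(values.shape[1])], values)
        seq = compute_linkage(data)
        return data, build_tree(seq, [[r] for r in ids], values.tolist())

    def test_metadata_keyed_by_leaf_id(self):
        values = np.array([[0.0, 0.0], [9.0, 9.0]])
        data, tree = self.tree_for(values, ["obj_a", "obj_b"])
        meta = MetadataTable(["obj_a", "obj_b"], ["Ki", "class"],
                             [[0.03, "positive"], [0.02, "negative"]])
        doc = build_document(tree, metadata=meta, feature_names=data.feature_names)
        leaf_of_a = next(
            nid for nid, nd in tree.nodes.items()
            if nd.is_leaf and nd.objects == ["obj_a"]
        )
        assert doc.metadata_nodes[leaf_of_a] == [0.03, "positive"]

    def test_data_block_only(self):
        values = np.array([[0.0], [1.0]])
        data, tree = self.tree_for(values, ["a", "b"])
        doc = build_document(tree, feature_names=data.feature_names)
        assert doc.metadata_nodes is None and doc.column_tree is None
        assert validate(doc) == []

    def test_column_tree_permutes_features_materially(self):
        # two distant rows, three columns of which #0 and #2 are nearly equal:
        # the column tree orders them adjacently, so leaf features are permuted
        values = np.array([[0.0, 5.0, 0.1], [1.0, 6.0, 1.1]])
        data = DataMatrix(["a", "b"], ["c0", "c1", "c2"], values)
        row_tree = build_tree(
            compute_linkage(data), [["a"], ["b"]], values.tolist()
        )
        col_tree = build_tree(compute_linkage(data, axis="column"))
        doc = build_document(row_tree, col_tree=col_tree, feature_names=data.feature_names)
        assert sorted(doc.feature_names) == ["c0", "c1", "c2"]
        assert doc.feature_names != ["c0", "c1", "c2"]  # genuinely permuted
        perm = [data.feature_names.index(f) for f in doc.feature_names]
        for nid in doc.row_tree.nodes:
            nd = doc.row_tree.nodes[nid]
            if nd.is_leaf:
                original = values[0 if nd.objects == ["a"] else 1]
                assert nd.features == [original[j] for j in perm]
        assert validate(doc) == []

    def test_unmatched_metadata_id_warns_and_drops(self):
        values = np.array([[0.0], [1.0]])
        data, tree = self.tree_for(values, ["a", "b"])
        meta = MetadataTable(["a", "b", "ghost"], ["m"], [[1], [2], [3]])
        with pytest.warns(UserWarning, match="1 metadata"):
            doc = build_document(tree, metadata=meta, feature_names=data.feature_names)
        assert all("ghost" not in v for v in doc.metadata_nodes.values())

    def test_column_tree_leaf_count_mismatch_is_error(self):
        values = np.array([[0.0, 1.0], [1.0, 2.0]])
        data, tree = self.tree_for(values, ["a", "b"])
        other = DataMatrix(["x", "y"], ["g0", "g1", "g2"],
                           np.array([[0, 1, 2], [3, 4, 5.0]]))
        col_tree = build_tree(compute_linkage(other, axis="column"))
        with pytest.raises(DocumentError, match="3 leaves"):
            build_document(tree, col_tree=col_tree, feature_names=data.feature_names)
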