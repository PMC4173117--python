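import numpy as np
import pytest

from conftest import random_matrix
from dendroheat import (
    DataMatrix,
    build_tree,
    compute_linkage,
    naive_linkage,
    tree_to_merges,
)

MONOTONE = ["single", "complete", "average", "ward", "weighted"]
ALL_METHODS = MONOTONE + ["centroid", "median"]


def one_d(*xs):
    return DataMatrix(
        [f"r{i}" for i in range(len(xs))], ["f"], np.array(xs, dtype=float)[:, None]
    )


def merge_heights(seq):
    """Map each merged leaf set to its height: order-independent comparison."""
    return dict(zip(seq.leaf_sets(), (m.height for m in seq.merges)))


class TestLinkageExamples:
    @pytest.mark.parametrize("fn", [compute_linkage, naive_linkage])
    def test_single_euclidean_three_points(self, fn):
        # brute force: closest pair (0,1) at 1; then min(10-0, 10-1) = 9
        seq = fn(one_d(0, 1, 10), "row", "single", "euclidean")
        assert [m.height for m in seq.merges] == [1.0, 9.0]
        assert seq.merges[0].size == 2 and seq.merges[1].size == 3

    @pytest.mark.parametrize("fn", [compute_linkage, naive_linkage])
    def test_identical_rows_merge_at_zero(self, fn):
        seq = fn(one_d(5, 5, 9), "row", "average", "euclidean")
        assert seq.merges[0].height == 0.0

    @pytest.mark.parametrize("fn", [compute_linkage, naive_linkage])
    def test_ward_singleton_pair_merges_at_euclidean_distance(self, fn):
        # closed form: d_ward(A, B) = sqrt(2*1*1/2) * ||a-b|| = ||a-b||
        data = DataMatrix(["a", "b"], ["x", "y"], np.array([[0.0, 0.0], [3.0, 4.0]]))
        seq = fn(data, "row", "ward", "euclidean")
        assert seq.merges[0].height == pytest.approx(5.0)

    def test_column_axis_transposes(self):
        data = DataMatrix(
            ["a", "b"], ["f1", "f2", "f3"], np.array([[0.0, 0.1, 9.0], [0.0, 0.1, 9.0]])
        )
        seq = compute_linkage(data, "column", "single", "euclidean")
        assert seq.n_leaves == 3
        first = seq.leaf_sets()[0]
        assert first == frozenset({0, 1})  # the two near-identical columns join first

    def test_naive_tie_break_prefers_smallest_index_pair(self):
        seq = naive_linkage(one_d(0, 0, 0, 0), "row", "single", "euclidean")
        assert (seq.merges[0].left, seq.merges[0].right) == (0, 1)
        assert all(m.height == 0 for m in seq.merges)


class TestLinkageErrors:
    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown linkage"):
            compute_linkage(one_d(0, 1), linkage="sparkle")

    def test_unknown_metric(self):
        with pytest.raises(ValueError, match="unknown distance"):
            compute_linkage(one_d(0, 1), distance="taxi")

    def test_fewer_than_two_items(self):
        with pytest.raises(ValueError, match="at least 2"):
            compute_linkage(one_d(0))

    def test_correlation_on_constant_vector(self):
        data = DataMatrix(["a", "b"], ["x", "y"], np.array([[1.0, 1.0], [0.0, 2.0]]))
        with pytest.raises(ValueError, match="constant"):
            compute_linkage(data, linkage="average", distance="correlation")

    def test_euclidean_only_methods_reject_other_metrics(self):
        with pytest.raises(ValueError, match="euclidean"):
            compute_linkage(one_d(0, 1), linkage="ward", distance="manhattan")


class TestOracleAgreement:
    """Fast path vs. definition-based O(n^3) agglomeration."""

    @pytest.mark.filterwarnings("ignore:.*inversion")
    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_random_instances_agree(self, method):
        rng = np.random.default_rng(123)
        metrics = (
            ["euclidean"]
            if method in ("ward", "centroid", "median")
            else ["euclidean", "manhattan", "cosine", "correlation"]
        )
        for trial in range(8):
            data = random_matrix(rng, int(rng.integers(4, 21)), 5)
            for metric in metrics:
                fast = merge_heights(compute_linkage(data, "row", method, metric))
                slow = merge_heights(naive_linkage(data, "row", method, metric))
                assert set(fast) == set(slow), f"{method}/{metric} topology differs"
                for key in fast:
                    assert fast[key] == pytest.approx(slow[key], abs=1e-9)

    @pytest.mark.parametrize("method", MONOTONE)
    def test_monotone_methods_have_nondecreasing_heights(self, method):
        rng = np.random.default_rng(5)
        for _ in range(5):
            seq = compute_linkage(random_matrix(rng, 15, 4), "row", method)
            heights = [m.height for m in seq.merges]
            assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_inversion_warning_for_centroid(self):
        # classic inversion: three points in a near-equilateral triangle
        data = DataMatrix(
            ["a", "b", "c"], ["x", "y"],
            np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 0.9]]),
        )
        with pytest.warns(UserWarning, match="inversion"):
            compute_linkage(data, linkage="centroid")


class TestBuildTree:
    def test_two_leaf_tree_matches_documented_shape(self):
        seq = compute_linkage(one_d(0, 3.32), "row", "single", "euclidean")
        tree = build_tree(seq, [["object_1"], ["object_2"]], [[0.0], [3.32]])
        root = tree.nodes[tree.root_id]
        assert tree.root_id == "node_0"
        assert root.distance == pytest.approx(3.32)
        assert {root.left, root.right} == {"leaf_0", "leaf_1"}
        assert root.count == 2
        assert root.parent is None

    def test_every_leaf_has_count_one_and_distance_zero(self, blob_data):
        data, _ = blob_data
        tree = build_tree(compute_linkage(data), [[r] for r in data.row_ids])
        for nid in tree.leaves():
            assert tree.nodes[nid].count == 1
            assert tree.nodes[nid].distance == 0.0

    def test_root_count_equals_leaf_count_random_trees(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(2, 25))
            tree = build_tree(compute_linkage(random_matrix(rng, n, 3)))
            assert tree.nodes[tree.root_id].count == n == len(tree.leaves())

    def test_child_orientation_left_has_smaller_min_leaf_index(self, blob_data):
        data, _ = blob_data
        tree = build_tree(compute_linkage(data))

        def min_leaf(nid):
            nd = tree.nodes[nid]
            if nd.is_leaf:
                return int(nid.split("_")[1])
            return min(min_leaf(nd.left), min_leaf(nd.right))

        for nid, nd in tree.nodes.items():
            if not nd.is_leaf:
                assert min_leaf(nd.left) < min_leaf(nd.right)

    def test_merge_extraction_roundtrip(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            seq = compute_linkage(random_matrix(rng, 12, 3))
            back = tree_to_merges(build_tree(seq))
            assert back.n_leaves == seq.n_leaves
            assert [(m.left, m.right, m.size) for m in back.merges] == [
                (m.left, m.right, m.size) for m in seq.merges
            ]
            assert [m.height for m in back.merges] == pytest.approx(
                [m.height for m in seq.merges]
            )

    def test_inconsistent_merge_sequence_rejected(self):
        from dendroheat import Merge, MergeSequence

        with pytest.raises(ValueError, match="twice"):
            MergeSequence(
                3,
                [Merge(0, 1, 1.0, 2), Merge(0, 3, 2.0, 3)],
            )
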