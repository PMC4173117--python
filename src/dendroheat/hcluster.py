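"""Agglomerative clustering of rows or columns and the ID-addressed merge tree.

Two routes produce the same merge sequence:

* :func:`compute_linkage` wraps the SciPy hierarchical-clustering engine, the
  production path.
* :func:`naive_linkage` agglomerates directly from the linkage definitions in
  O(n^3), recomputing every inter-cluster distance from scratch at each step.
  It exists so the fast path can be checked against first principles on small
  instances.

A :class:`MergeSequence` uses the standard indexing: original observations are
clusters ``0..n-1`` and merge ``i`` creates cluster ``n+i``.  The sequence is
turned into a :class:`DendrogramTree` whose nodes carry the parent/child
links, leaf counts and merge distances that the heatmap document serializes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial import distance as ssd

from .tabular_io import DataMatrix

__all__ = [
    "Merge",
    "MergeSequence",
    "TreeNode",
    "DendrogramTree",
    "LINKAGE_METHODS",
    "DISTANCE_METRICS",
    "MONOTONE_METHODS",
    "compute_linkage",
    "naive_linkage",
    "build_tree",
    "tree_to_merges",
]

LINKAGE_METHODS = frozenset(
    {"single", "complete", "average", "ward", "centroid", "median", "weighted"}
)
#: methods whose merge heights are guaranteed non-decreasing
MONOTONE_METHODS = frozenset({"single", "complete", "average", "ward", "weighted"})
#: methods defined only for Euclidean geometry
_EUCLIDEAN_ONLY = frozenset({"ward", "centroid", "median"})

DISTANCE_METRICS = frozenset({"euclidean", "manhattan", "correlation", "cosine", "hamming"})
_SCIPY_METRIC = {"manhattan": "cityblock"}


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: member cluster indices, merge height, merged leaf count."""

    left: int
    right: int
    height: float
    size: int


@dataclass
class MergeSequence:
    """Ordered n-1 merges; cluster ``n + i`` is created by merge ``i``."""

    n_leaves: int
    merges: list[Merge] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.n_leaves
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves, got {len(self.merges)}")
        used: set[int] = set()
        sizes = {i: 1 for i in range(n)}
        for i, m in enumerate(self.merges):
            for member in (m.left, m.right):
                if member in used:
                    raise ValueError(f"cluster {member} used as a member twice")
                if member not in sizes:
                    raise ValueError(f"merge {i} references unknown cluster {member}")
                used.add(member)
            if m.height < 0:
                raise ValueError(f"negative merge height at step {i}")
            if m.size != sizes[m.left] + sizes[m.right]:
                raise ValueError(f"merge {i} size {m.size} != sum of member sizes")
            sizes[n + i] = m.size
        if self.merges and self.merges[-1].size != n:
            raise ValueError("final merge must contain every leaf")

    def leaf_sets(self) -> list[frozenset[int]]:
        """Leaf membership of every merged cluster, in merge order."""
        members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(self.n_leaves)}
        out = []
        for i, m in enumerate(self.merges):
            s = members[m.left] | members[m.right]
            members[self.n_leaves + i] = s
            out.append(s)
        return out


@dataclass
class TreeNode:
    parent: str | None = None
    left: str | None = None
    right: str | None = None
    count: int = 1
    distance: float = 0.0
    features: list[float] | None = None
    objects: list[str] | None = None
    extra: dict = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.left is None and self.right is None


@dataclass
class DendrogramTree:
    """ID-addressed binary merge tree; exactly one node (the root) has no parent."""

    nodes: dict[str, TreeNode]
    root_id: str

    def leaves(self) -> list[str]:
        return [nid for nid, node in self.nodes.items() if node.is_leaf]

    def n_leaves(self) -> int:
        return self.nodes[self.root_id].count


def _point_metric(metric: str):
    """Point-to-point distance computed from the textbook formula."""
    if metric == "euclidean":
        return lambda a, b: float(np.sqrt(np.sum((a - b) ** 2)))
    if metric == "manhattan":
        return lambda a, b: float(np.sum(np.abs(a - b)))
    if metric == "cosine":
        def cos(a, b):
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            return float(1.0 - np.dot(a, b) / (na * nb))
        return cos
    if metric == "correlation":
        def corr(a, b):
            ac, bc = a - a.mean(), b - b.mean()
            return float(1.0 - np.dot(ac, bc) / (np.linalg.norm(ac) * np.linalg.norm(bc)))
        return corr
    if metric == "hamming":
        return lambda a, b: float(np.mean(a != b))
    raise ValueError(f"unknown distance metric {metric!r}")


def _check_inputs(data: DataMatrix, axis: str, linkage: str, metric: str) -> np.ndarray:
    if axis not in ("row", "column"):
        raise ValueError(f"axis must be 'row' or 'column', not {axis!r}")
    if linkage not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage method {linkage!r}")
    if metric not in DISTANCE_METRICS:
        raise ValueError(f"unknown distance metric {metric!r}")
    if linkage in _EUCLIDEAN_ONLY and metric != "euclidean":
        raise ValueError(f"{linkage} linkage requires the euclidean metric")
    X = data.values if axis == "row" else data.values.T
    if X.shape[0] < 2:
        raise ValueError(f"need at least 2 items on the {axis} axis, got {X.shape[0]}")
    if metric == "correlation" and np.any(np.std(X, axis=1) == 0):
        raise ValueError("correlation metric is undefined for a constant vector")
    if metric == "cosine" and np.any(np.linalg.norm(X, axis=1) == 0):
        raise ValueError("cosine metric is undefined for a zero vector")
    return np.asarray(X, dtype=float)


def _clip_height(h: float) -> float:
    # floating-point roundoff in cosine/correlation can yield ~-1e-16
    if -1e-9 < h < 0.0:
        return 0.0
    return h


def _orient(left: int, right: int, min_leaf: dict[int, int]) -> tuple[int, int]:
    # left child is the member whose smallest original leaf index is smaller
    if min_leaf[left] <= min_leaf[right]:
        return left, right
    return right, left


def _warn_inversions(merges: list[Merge], linkage: str) -> None:
    heights = [m.height for m in merges]
    if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
        if linkage in MONOTONE_METHODS:
            raise AssertionError(f"{linkage} linkage produced a height inversion")
        warnings.warn(
            f"{linkage} linkage produced height inversions (non-monotone dendrogram)",
            stacklevel=3,
        )


def compute_linkage(
    data: DataMatrix,
    axis: str = "row",
    linkage: str = "ward",
    distance: str = "euclidean",
) -> MergeSequence:
    """Cluster rows (or columns, transposing first) into a merge sequence.

    Defaults mirror the pipeline's standard choice: Ward linkage with the
    Euclidean distance.  Heights follow the convention where two singletons
    under Ward merge at their Euclidean distance.
    """
    X = _check_inputs(data, axis, linkage, distance)
    Z = hierarchy.linkage(X, method=linkage, metric=_SCIPY_METRIC.get(distance, distance))
    n = X.shape[0]
    min_leaf = {i: i for i in range(n)}
    merges: list[Merge] = []
    for i in range(n - 1):
        a, b = int(Z[i, 0]), int(Z[i, 1])
        left, right = _orient(a, b, min_leaf)
        merges.append(Merge(left, right, _clip_height(float(Z[i, 2])), int(Z[i, 3])))
        min_leaf[n + i] = min(min_leaf[a], min_leaf[b])
    _warn_inversions(merges, linkage)
    return MergeSequence(n, merges)


def naive_linkage(
    data: DataMatrix,
    axis: str = "row",
    linkage: str = "ward",
    distance: str = "euclidean",
) -> MergeSequence:
    """Direct O(n^3) agglomeration from the linkage definitions (test oracle).

    At every step each inter-cluster distance is recomputed from its
    definition over the raw points: single/complete/average from the
    cross-pair point distances, Ward from the between-centroid increase in
    within-cluster sum of squares, centroid/median from (recursively
    maintained) cluster centres, and weighted (WPGMA) from its defining
    recursion.  Ties are broken by merging the pair with the lexicographically
    smallest (min index, max index).
    """
    X = _check_inputs(data, axis, linkage, distance)
    n = X.shape[0]
    dist = _point_metric(distance)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dist(X[i], X[j])

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    centres: dict[int, np.ndarray] = {i: X[i].astype(float) for i in range(n)}
    min_leaf = {i: i for i in range(n)}
    # pairwise cluster distances; only 'weighted' updates recursively,
    # everything else is recomputed from the definition on demand
    wpgma: dict[frozenset[int], float] = {
        frozenset((i, j)): D[i, j] for i in range(n) for j in range(i + 1, n)
    }

    def cluster_distance(a: int, b: int) -> float:
        A, B = members[a], members[b]
        if linkage == "single":
            return float(D[np.ix_(A, B)].min())
        if linkage == "complete":
            return float(D[np.ix_(A, B)].max())
        if linkage == "average":
            return float(D[np.ix_(A, B)].mean())
        if linkage == "ward":
            ca, cb = X[A].mean(axis=0), X[B].mean(axis=0)
            na, nb = len(A), len(B)
            return float(np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(ca - cb))
        if linkage == "centroid":
            return float(np.linalg.norm(X[A].mean(axis=0) - X[B].mean(axis=0)))
        if linkage == "median":
            return float(np.linalg.norm(centres[a] - centres[b]))
        if linkage == "weighted":
            return wpgma[frozenset((a, b))]
        raise AssertionError(linkage)

    active = set(range(n))
    merges: list[Merge] = []
    for step in range(n - 1):
        best_key = None
        best_d = np.inf
        for a in sorted(active):
            for b in sorted(active):
                if b <= a:
                    continue
                d = cluster_distance(a, b)
                if d < best_d - 1e-15 or (abs(d - best_d) <= 1e-15 and (best_key is None or (a, b) < best_key)):
                    best_d = d
                    best_key = (a, b)
        a, b = best_key  # type: ignore[misc]
        new = n + step
        members[new] = members[a] + members[b]
        centres[new] = 0.5 * (centres[a] + centres[b])
        min_leaf[new] = min(min_leaf[a], min_leaf[b])
        if linkage == "weighted":
            for other in active:
                if other in (a, b):
                    continue
                wpgma[frozenset((new, other))] = 0.5 * (
                    wpgma[frozenset((a, other))] + wpgma[frozenset((b, other))]
                )
        active.discard(a)
        active.discard(b)
        active.add(new)
        left, right = _orient(a, b, min_leaf)
        merges.append(Merge(left, right, _clip_height(float(best_d)), len(members[new])))
    _warn_inversions(merges, linkage)
    return MergeSequence(n, merges)


def build_tree(
    merges: MergeSequence,
    leaf_objects: list[list[str]] | None = None,
    leaf_features: list[list[float]] | None = None,
) -> DendrogramTree:
    """Convert a merge sequence into the ID-addressed dendrogram tree.

    Leaves are named ``leaf_0..leaf_{n-1}`` by input row order and inner nodes
    ``node_0..node_{n-2}`` by merge order.  Row-axis trees carry per-leaf
    ``objects`` (the data-point IDs of the heatmap row) and ``features``;
    column-axis trees carry neither.
    """
    n = merges.n_leaves
    if leaf_objects is not None and len(leaf_objects) != n:
        raise ValueError(f"{len(leaf_objects)} object lists for {n} leaves")
    if leaf_features is not None and len(leaf_features) != n:
        raise ValueError(f"{len(leaf_features)} feature lists for {n} leaves")

    def name(idx: int) -> str:
        return f"leaf_{idx}" if idx < n else f"node_{idx - n}"

    nodes: dict[str, TreeNode] = {}
    for i in range(n):
        nodes[f"leaf_{i}"] = TreeNode(
            count=1,
            distance=0.0,
            features=list(leaf_features[i]) if leaf_features is not None else None,
            objects=list(leaf_objects[i]) if leaf_objects is not None else None,
        )
    for i, m in enumerate(merges.merges):
        nid = f"node_{i}"
        left, right = name(m.left), name(m.right)
        nodes[nid] = TreeNode(left=left, right=right, count=m.size, distance=m.height)
        nodes[left].parent = nid
        nodes[right].parent = nid
    root = f"node_{n - 2}" if n > 1 else "leaf_0"
    return DendrogramTree(nodes, root)


def tree_to_merges(tree: DendrogramTree) -> MergeSequence:
    """Extract the merge sequence back out of a tree built by :func:`build_tree`."""
    leaf_ids = sorted(
        (nid for nid, nd in tree.nodes.items() if nd.is_leaf),
        key=lambda s: int(s.rsplit("_", 1)[1]),
    )
    inner_ids = sorted(
        (nid for nid, nd in tree.nodes.items() if not nd.is_leaf),
        key=lambda s: int(s.rsplit("_", 1)[1]),
    )
    n = len(leaf_ids)
    index = {nid: i for i, nid in enumerate(leaf_ids)}
    merges: list[Merge] = []
    for i, nid in enumerate(inner_ids):
        nd = tree.nodes[nid]
        index[nid] = n + i
        merges.append(Merge(index[nd.left], index[nd.right], nd.distance, nd.count))
    return MergeSequence(n, merges)
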