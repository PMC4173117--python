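"""Row compression: cut the row dendrogram into k groups and aggregate each.

Large matrices render slowly and hide broad motifs; compressing the heatmap
to k rows cuts the dendrogram at the k clusters present just before its last
k-1 merges and replaces each cluster with a single vector of per-feature
means or medians.  The IDs of the original data points travel along in each
reduced row's objects list.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .hcluster import MergeSequence
from .tabular_io import DataMatrix, MetadataTable

__all__ = ["RowGrouping", "cut_to_k", "aggregate", "aggregate_metadata"]

STATS = ("mean", "median")


@dataclass
class RowGrouping:
    """Ordered partition of the original row indices into k groups."""

    groups: list[list[int]]
    stat: str | None = None

    def __post_init__(self) -> None:
        flat = [i for g in self.groups for i in g]
        if len(flat) != len(set(flat)):
            raise ValueError("groups overlap")
        if self.stat is not None and self.stat not in STATS:
            raise ValueError(f"stat must be one of {STATS}, not {self.stat!r}")

    @property
    def k(self) -> int:
        return len(self.groups)

    def n_rows(self) -> int:
        return sum(len(g) for g in self.groups)


def cut_to_k(merges: MergeSequence, k: int) -> RowGrouping:
    """Undo the last k-1 merges: the k clusters present just before them.

    Groups are ordered by their smallest original row index, which makes the
    cut deterministic; the reduced matrix is re-clustered afterwards anyway.
    """
    n = merges.n_leaves
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = set(range(n))
    for i, m in enumerate(merges.merges[: n - k]):
        new = n + i
        members[new] = members[m.left] + members[m.right]
        active.discard(m.left)
        active.discard(m.right)
        active.add(new)
    groups = sorted((sorted(members[c]) for c in active), key=lambda g: g[0])
    return RowGrouping(groups)


def aggregate(
    data: DataMatrix, grouping: RowGrouping, stat: str = "mean"
) -> tuple[DataMatrix, list[list[str]]]:
    """Collapse each group to one row; returns the reduced matrix and, per
    reduced row, the list of original row IDs it represents."""
    if stat not in STATS:
        raise ValueError(f"stat must be one of {STATS}, not {stat!r}")
    if grouping.n_rows() != data.n_rows:
        raise ValueError("grouping does not partition the data rows")
    fn = np.mean if stat == "mean" else np.median
    rows = []
    objects: list[list[str]] = []
    for g in grouping.groups:
        rows.append(fn(data.values[g, :], axis=0))
        objects.append([data.row_ids[i] for i in g])
    reduced = DataMatrix(
        [f"group_{i}" for i in range(len(grouping.groups))],
        list(data.feature_names),
        np.vstack(rows),
    )
    return reduced, objects


def aggregate_metadata(
    meta: MetadataTable, grouping: RowGrouping, stat: str = "mean"
) -> MetadataTable:
    """Aggregate metadata over the same grouping: numeric columns by *stat*,
    categorical columns by most-frequent label (ties broken lexicographically);
    missing cells are ignored."""
    if stat not in STATS:
        raise ValueError(f"stat must be one of {STATS}, not {stat!r}")
    fn = np.mean if stat == "mean" else np.median
    values: list[list[object]] = []
    for g in grouping.groups:
        row: list[object] = []
        for j, ctype in enumerate(meta.column_types):
            cells = [meta.values[i][j] for i in g if meta.values[i][j] is not None]
            if not cells:
                row.append(None)
            elif ctype == "numeric":
                row.append(float(fn(np.array(cells, dtype=float))))
            else:
                counts = Counter(str(c) for c in cells)
                top = max(counts.values())
                row.append(min(label for label, c in counts.items() if c == top))
        values.append(row)
    return MetadataTable(
        [f"group_{i}" for i in range(len(grouping.groups))],
        list(meta.feature_names),
        values,
        list(meta.column_types),
    )
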