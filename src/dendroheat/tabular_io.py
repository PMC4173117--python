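"""Reading and writing the delimiter-separated data and metadata tables.

The data table holds one data point per row: the first column is the row ID,
the remaining columns are numeric features.  A metadata table uses the same
keying but its columns may be numeric (e.g. an affinity constant) or
categorical (e.g. a class label); metadata are displayed beside the heatmap
but never clustered.
"""

from __future__ import annotations

import csv
import io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DataMatrix",
    "MetadataTable",
    "TableFormatError",
    "read_data_table",
    "read_metadata_table",
    "write_data_table",
    "write_metadata_table",
    "join_metadata",
]

MISSING = None  # marker used for metadata cells absent after a join


class TableFormatError(ValueError):
    """Raised for malformed input tables (duplicate IDs, ragged rows, bad cells)."""


@dataclass
class DataMatrix:
    """Row IDs x feature names with a finite numeric value grid."""

    row_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # shape (n_rows, n_features), float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D grid")
        n, m = self.values.shape
        if len(self.row_ids) != n:
            raise ValueError(f"{len(self.row_ids)} row IDs for {n} value rows")
        if len(self.feature_names) != m:
            raise ValueError(f"{len(self.feature_names)} feature names for {m} columns")
        if len(set(self.row_ids)) != n:
            seen: set[str] = set()
            for rid in self.row_ids:
                if rid in seen:
                    raise TableFormatError(f"duplicate row ID {rid!r}")
                seen.add(rid)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DataMatrix):
            return NotImplemented
        return (
            self.row_ids == other.row_ids
            and self.feature_names == other.feature_names
            and self.values.shape == other.values.shape
            and bool(np.array_equal(self.values, other.values))
        )


@dataclass
class MetadataTable:
    """Row IDs x metadata features; each column homogeneously numeric or categorical.

    Cells are floats, strings, or ``None`` for missing entries introduced by
    :func:`join_metadata`.
    """

    row_ids: list[str]
    feature_names: list[str]
    values: list[list[object]]
    column_types: list[str] = field(default_factory=list)  # "numeric" | "categorical"

    def __post_init__(self) -> None:
        if len(set(self.row_ids)) != len(self.row_ids):
            raise TableFormatError("duplicate row IDs in metadata")
        for row in self.values:
            if len(row) != len(self.feature_names):
                raise ValueError("metadata rows must be rectangular")
        if not self.column_types:
            self.column_types = [
                _infer_column_type([row[j] for row in self.values])
                for j in range(len(self.feature_names))
            ]
        elif len(self.column_types) != len(self.feature_names):
            raise ValueError("one column type per feature required")

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    def row(self, row_id: str) -> list[object]:
        return self.values[self.row_ids.index(row_id)]


def _infer_column_type(cells: list[object]) -> str:
    present = [c for c in cells if c is not None]
    if present and all(isinstance(c, (int, float)) and not isinstance(c, bool) for c in present):
        return "numeric"
    return "categorical"


def _read_rows(text: str, delimiter: str) -> list[tuple[int, list[str]]]:
    if not isinstance(delimiter, str) or len(delimiter) != 1:
        raise ValueError("delimiter must be a single character")
    # csv handles quoting; splitlines tolerates \n and \r\n
    reader = csv.reader(io.StringIO(text, newline=""), delimiter=delimiter)
    rows = [(i + 1, row) for i, row in enumerate(reader) if row]
    if not rows:
        raise TableFormatError("empty input")
    return rows


def _parse_number(cell: str) -> float | None:
    try:
        v = float(cell)
    except ValueError:
        return None
    return v if math.isfinite(v) else None


def read_data_table(
    text: str,
    delimiter: str = ",",
    has_header: bool = False,
    missing: str = "error",
) -> DataMatrix:
    """Parse a delimited table into a :class:`DataMatrix`.

    The first column always contains the row IDs; if *has_header* the first
    row (minus its first cell) names the features, otherwise names are
    auto-generated as ``feature_1..m``.  *missing* is ``"error"`` (any
    non-numeric cell aborts with its coordinates) or ``"drop"`` (the affected
    row is removed).
    """
    rows = _read_rows(text, delimiter)
    if has_header:
        feature_names = [c.strip() for c in rows[0][1][1:]]
        rows = rows[1:]
        if not rows:
            raise TableFormatError("no data rows below the header")
    else:
        feature_names = []

    width = len(rows[0][1])
    if width < 2:
        raise TableFormatError("a data table needs an ID column plus at least one feature")
    if not feature_names:
        feature_names = [f"feature_{j + 1}" for j in range(width - 1)]
    elif len(feature_names) != width - 1:
        raise TableFormatError(
            f"header names {len(feature_names)} features but rows have {width - 1}"
        )

    row_ids: list[str] = []
    grid: list[list[float]] = []
    seen: set[str] = set()
    for lineno, cells in rows:
        if len(cells) != width:
            raise TableFormatError(
                f"ragged row at line {lineno}: expected {width} cells, found {len(cells)}"
            )
        rid = cells[0].strip()
        parsed: list[float] = []
        bad = None
        for j, cell in enumerate(cells[1:]):
            v = _parse_number(cell.strip())
            if v is None:
                bad = (lineno, j + 2, cell)
                break
            parsed.append(v)
        if bad is not None:
            if missing == "drop":
                continue
            lineno, col, cell = bad
            raise TableFormatError(
                f"non-numeric cell {cell!r} at line {lineno}, column {col}"
            )
        if rid in seen:
            raise TableFormatError(f"duplicate row ID {rid!r}")
        seen.add(rid)
        row_ids.append(rid)
        grid.append(parsed)
    if not grid:
        raise TableFormatError("no rows survived missing-value filtering")
    return DataMatrix(row_ids, feature_names, np.array(grid, dtype=float))


def read_metadata_table(
    text: str,
    delimiter: str = ",",
    has_header: bool = False,
) -> MetadataTable:
    """Parse a metadata table; each column is numeric iff every cell parses as a number."""
    rows = _read_rows(text, delimiter)
    if has_header:
        feature_names = [c.strip() for c in rows[0][1][1:]]
        rows = rows[1:]
        if not rows:
            raise TableFormatError("no metadata rows below the header")
    else:
        feature_names = []

    width = len(rows[0][1])
    if width < 2:
        raise TableFormatError("a metadata table needs an ID column plus at least one column")
    if not feature_names:
        feature_names = [f"feature_{j + 1}" for j in range(width - 1)]
    elif len(feature_names) != width - 1:
        raise TableFormatError(
            f"header names {len(feature_names)} features but rows have {width - 1}"
        )

    row_ids: list[str] = []
    raw: list[list[str]] = []
    seen: set[str] = set()
    for lineno, cells in rows:
        if len(cells) != width:
            raise TableFormatError(
                f"ragged row at line {lineno}: expected {width} cells, found {len(cells)}"
            )
        rid = cells[0].strip()
        if rid in seen:
            raise TableFormatError(f"duplicate row ID {rid!r}")
        seen.add(rid)
        row_ids.append(rid)
        raw.append([c.strip() for c in cells[1:]])

    n_cols = width - 1
    columns: list[list[object]] = []
    types: list[str] = []
    for j in range(n_cols):
        cells = [row[j] for row in raw]
        numbers = [_parse_number(c) for c in cells]
        if all(v is not None for v in numbers):
            columns.append(list(numbers))
            types.append("numeric")
        else:  # mixed columns fall back to categorical
            columns.append(list(cells))
            types.append("categorical")
    values = [[columns[j][i] for j in range(n_cols)] for i in range(len(row_ids))]
    return MetadataTable(row_ids, feature_names, values, types)


def _format_cell(v: object) -> str:
    if v is None:
        return ""
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return str(v)


def write_data_table(data: DataMatrix, delimiter: str = ",", header: bool = True) -> str:
    """Serialize a DataMatrix back to delimited text (round-trips with read_data_table)."""
    buf = io.StringIO()
    w = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    if header:
        w.writerow(["id", *data.feature_names])
    for rid, row in zip(data.row_ids, data.values):
        w.writerow([rid, *(repr(float(v)) for v in row)])
    return buf.getvalue()


def write_metadata_table(meta: MetadataTable, delimiter: str = ",", header: bool = True) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    if header:
        w.writerow(["id", *meta.feature_names])
    for rid, row in zip(meta.row_ids, meta.values):
        w.writerow([rid, *(_format_cell(v) for v in row)])
    return buf.getvalue()


def join_metadata(data: DataMatrix, meta: MetadataTable) -> MetadataTable:
    """Align metadata rows to ``data.row_ids``.

    Data rows absent from the metadata receive ``None`` cells; metadata rows
    that match no data row are dropped (a warning reports how many).
    """
    index = {rid: i for i, rid in enumerate(meta.row_ids)}
    n_cols = len(meta.feature_names)
    values: list[list[object]] = []
    matched = 0
    for rid in data.row_ids:
        i = index.get(rid)
        if i is None:
            values.append([None] * n_cols)
        else:
            values.append(list(meta.values[i]))
            matched += 1
    dropped = meta.n_rows - matched
    if dropped:
        warnings.warn(
            f"{dropped} metadata row(s) matched no data row and were dropped",
            stacklevel=2,
        )
    return MetadataTable(list(data.row_ids), list(meta.feature_names), values, list(meta.column_types))
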