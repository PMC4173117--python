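"""Min-max feature scaling and the normalized-cluster / original-display pairing.

Features measured on very different scales (molecular weight in the hundreds
versus logP in single digits) would otherwise dominate a Euclidean
clustering; scaling each feature to [0, 1] with

    x' = (x - min(x)) / (max(x) - min(x))

balances their influence.  The display pairing lets the dendrogram be built
on the scaled values while the document's heatmap still shows the original
ones, so row order is always that of the normalized clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tabular_io import DataMatrix

__all__ = ["ScalingParams", "DisplayPairing", "fit_minmax", "apply_minmax", "pair_display_values"]


@dataclass
class ScalingParams:
    """Per-feature (min, max) pairs captured from a fitted matrix."""

    mins: dict[str, float]
    maxs: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.mins) != set(self.maxs):
            raise ValueError("mins and maxs must cover the same features")
        for name, lo in self.mins.items():
            if lo > self.maxs[name]:
                raise ValueError(f"min > max for feature {name!r}")


@dataclass
class DisplayPairing:
    """Clustering consumes ``cluster_values``; leaf features carry ``display_values``."""

    cluster_values: DataMatrix
    display_values: DataMatrix


def fit_minmax(data: DataMatrix) -> ScalingParams:
    """Record exact per-column minima and maxima."""
    if data.n_rows == 0:
        raise ValueError("cannot fit scaling on an empty matrix")
    lo = data.values.min(axis=0)
    hi = data.values.max(axis=0)
    names = data.feature_names
    return ScalingParams(dict(zip(names, lo.tolist())), dict(zip(names, hi.tolist())))


def apply_minmax(data: DataMatrix, params: ScalingParams) -> DataMatrix:
    """Apply x' = (x - min) / (max - min) column-wise.

    A constant feature (max == min) maps to 0 everywhere, keeping the output
    inside [0, 1].
    """
    missing = [f for f in data.feature_names if f not in params.mins]
    if missing:
        raise KeyError(f"no scaling parameters for feature(s) {missing}")
    lo = np.array([params.mins[f] for f in data.feature_names])
    hi = np.array([params.maxs[f] for f in data.feature_names])
    span = hi - lo
    safe = np.where(span == 0, 1.0, span)
    scaled = (data.values - lo) / safe
    scaled[:, span == 0] = 0.0
    return DataMatrix(list(data.row_ids), list(data.feature_names), scaled)


def pair_display_values(normalized: DataMatrix, original: DataMatrix) -> DisplayPairing:
    """Pair a scaled matrix (for clustering) with the original one (for display)."""
    if normalized.row_ids != original.row_ids:
        raise ValueError("row IDs differ between the normalized and original matrices")
    if normalized.feature_names != original.feature_names:
        raise ValueError("feature names differ between the normalized and original matrices")
    return DisplayPairing(cluster_values=normalized, display_values=original)
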